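"""Synthetic annotated mitogenomes and evolved alignments.

The generator emulates the statistical structure of a fish mitochondrial
genome so every analysis stage can be exercised offline: a circular
~16.6-17.1 kb molecule with 13 PCGs, 22 tRNAs, 2 rRNAs and a control
region; canonical-vertebrate or parrotfish-rearranged tRNA order (the
latter with tRNA-Met translocated between tRNA-Ile and tRNA-Gln and a
degenerate tRNA-Met copy filling the long tRNA-Gln-to-ND2 spacer);
configurable genome-wide base composition and AT/GC skew (including the
negative AT skew seen in some lineages); planted ATP8/ATP6, ND4L/ND4 and
ND5/ND6 overlap motifs; truncated stop codons; and control-region CSB
plants.  Gene lengths and spacers default to a published parrotfish
feature-table geometry so fixture assertions match printed values.

Protein-coding genes are sampled codon-wise from a 60-sense-codon joint
distribution solved (by iterative proportional fitting) so that the
position-averaged base marginals hit the composition target exactly while
third positions carry an AT-biased wobble preference; stop codons are
never produced in frame.  All generators are deterministic given the
mandatory seed.

Alignments evolve under a Kimura two-parameter process (optionally with
gamma rate heterogeneity) on star or symmetric trees, and coding
sequences under a 60-state codon model in which nonsynonymous changes are
accepted with relative rate omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm

from .codons import SENSE_CODONS, STOP_CODONS
from .io import GeneFeature, MitoGenome

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_STOP_IDX = [tuple(_CODE[b] for b in s) for s in sorted(STOP_CODONS)]
_SENSE = sorted(SENSE_CODONS)
_SENSE_BASES = np.array([[_CODE[b] for b in c] for c in _SENSE], dtype=np.int8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def base_probs(at_content: float, at_skew: float, gc_skew: float) -> np.ndarray:
    """Per-base probabilities (A,C,G,T order) from content/skew targets."""
    at, gc = at_content, 1.0 - at_content
    p = np.array([
        at * (1 + at_skew) / 2,
        gc * (1 - gc_skew) / 2,
        gc * (1 + gc_skew) / 2,
        at * (1 - at_skew) / 2,
    ])
    if (p <= 0).any():
        raise ValueError("composition targets imply a non-positive base probability")
    return p


def codon_joint(
    p_target: np.ndarray,
    wobble_weights: Optional[Mapping[str, float]] = None,
    n_iter: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Sense-codon joint distribution matching position-averaged marginals.

    Returns ``(joint, marginals)`` where ``joint`` is a length-60
    probability vector over :data:`SENSE_CODONS` (sorted) and ``marginals``
    the realised (3, 4) per-position base marginals.  When wobble weights
    are given, the third-position marginal is tilted by them and positions
    one and two compensate so the codon-averaged marginal still equals
    ``p_target``; stop-codon exclusion is folded in by iterative
    proportional fitting.
    """
    p = np.asarray(p_target, dtype=float)
    if wobble_weights is None:
        desired3 = p.copy()
    else:
        w = np.array([wobble_weights[b] for b in _BASES])
        desired3 = p * w
        desired3 /= desired3.sum()
    desired12 = np.clip((3 * p - desired3) / 2, 1e-4, None)
    desired12 /= desired12.sum()
    desired = [desired12, desired12, desired3]

    q = [d.copy() for d in desired]
    stop_mask = np.ones((4, 4, 4), dtype=bool)
    for i, j, k in _STOP_IDX:
        stop_mask[i, j, k] = False
    for _ in range(n_iter):
        cube = np.einsum("i,j,k->ijk", q[0], q[1], q[2]) * stop_mask
        cube /= cube.sum()
        for pos in range(3):
            marg = cube.sum(axis=tuple(a for a in range(3) if a != pos))
            q[pos] = q[pos] * desired[pos] / np.clip(marg, 1e-12, None)
            q[pos] /= q[pos].sum()
    cube = np.einsum("i,j,k->ijk", q[0], q[1], q[2]) * stop_mask
    cube /= cube.sum()
    joint = np.array([cube[tuple(b)] for b in _SENSE_BASES])
    joint /= joint.sum()
    marginals = np.stack([
        cube.sum(axis=(1, 2)), cube.sum(axis=(0, 2)), cube.sum(axis=(0, 1))
    ])
    return joint, marginals


def random_coding_sequence(n_codons: int, seed: int,
                           p_target: Sequence[float] = (0.25,) * 4) -> str:
    """Random stop-free coding sequence drawn from the sense-codon joint."""
    rng = np.random.default_rng(seed)
    joint, _ = codon_joint(np.asarray(p_target))
    idx = rng.choice(len(_SENSE), size=n_codons, p=joint)
    return "".join(_SENSE[i] for i in idx)


# ---------------------------------------------------------------------------
# genome specification

#: default overlap motifs, keyed by (upstream, downstream); lengths must
#: equal the planned overlaps.  The ATP8/ATP6 16-mer carries both genes'
#: reading frames (ATP8's TAG stop, ATP6's CTG start); ND4L/ND4 share the
#: 7-mer around ND4's ATG; the ND5/ND6 4-mer holds ND5's TAA stop on the H
#: strand and ND6's TAA stop on the L strand.
DEFAULT_OVERLAP_MOTIFS = {
    ("ATP8", "ATP6"): "CTGACCTTGGCACTAG",
    ("ND4L", "ND4"): "ATGCTAA",
    ("ND5", "ND6"): "TTAA",
}

DEFAULT_WOBBLE_WEIGHTS = {"A": 1.7, "T": 1.2, "C": 0.9, "G": 0.45}


@dataclass
class GenomeSpec:
    """Recipe for one synthetic annotated mitogenome."""

    seed: int
    template: str = "parrotfish"          # or "vertebrate"
    at_content: float = 0.55              # whole genome, H strand
    at_skew: float = 0.05
    gc_skew: float = -0.25
    cr_at_content: Optional[float] = 0.63  # CR richer in A+T; None = uniform
    cr_length: int = 1242
    wobble_weights: Optional[Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_WOBBLE_WEIGHTS))
    overlap_motifs: Mapping[tuple[str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_OVERLAP_MOTIFS))
    psi_similarity: float = 0.8           # pseudo-tRNA-Met identity target
    csb_blocks: tuple[str, ...] = ("CSB-D", "CSB-I", "CSB-II")
    genome_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.template not in ("parrotfish", "vertebrate"):
            raise ValueError("template must be 'parrotfish' or 'vertebrate'")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def _gene_plan(spec: GenomeSpec) -> list[dict]:
    """(name, kind, length, igs-after, strand, codons) list in circle order."""
    import pandas as pd
    from importlib import resources
    plan = []
    with resources.as_file(resources.files("mitocomp.data")
                           / "calotomus_carolinus_table.tsv") as p:
        df = pd.read_csv(p, sep="\t").fillna("")
    for _, row in df.iterrows():
        plan.append({
            "name": str(row["gene"]), "kind": str(row["kind"]),
            "length": int(row["length"]), "igs": int(row["intergenic"]),
            "strand": "L" if str(row["strand"]) == "L" else "H",
            "start_codon": str(row["start_codon"]) or None,
            "stop_codon": str(row["stop_codon"]) or None,
            "anticodon": str(row["anticodon"]) or None,
        })
    by_name = {p["name"]: p for p in plan}
    by_name["CR"]["length"] = spec.cr_length
    if spec.template == "vertebrate":
        met = by_name["tRNA-Met"]
        gln = by_name["tRNA-Gln"]
        plan.remove(met)
        plan.insert(plan.index(gln) + 1, met)
        by_name["tRNA-Ile"]["igs"] = 1
        gln["igs"] = 0
        met["igs"] = 1
    return plan


def _mutate_copy(rng: np.random.Generator, seq: np.ndarray,
                 target_len: int, similarity: float) -> np.ndarray:
    """Shrink/grow a sequence to target_len and mutate to ~similarity identity."""
    out = seq.copy()
    while len(out) > target_len:
        out = np.delete(out, rng.integers(len(out)))
    while len(out) < target_len:
        pos = rng.integers(len(out) + 1)
        out = np.insert(out, pos, rng.integers(4))
    n_mut = int(round((1 - similarity) * target_len))
    pos = rng.choice(target_len, size=n_mut, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def _sample_constrained_codon(rng: np.random.Generator, joint: np.ndarray,
                              fixed: np.ndarray) -> np.ndarray:
    mask = np.ones(len(_SENSE), dtype=bool)
    for k in range(3):
        if fixed[k] >= 0:
            mask &= _SENSE_BASES[:, k] == fixed[k]
    w = joint * mask
    if w.sum() == 0:
        raise ValueError("infeasible codon constraint (fixed bases spell a stop)")
    return _SENSE_BASES[rng.choice(len(_SENSE), p=w / w.sum())].copy()


def make_genome(spec: GenomeSpec) -> tuple[MitoGenome, dict]:
    """Build one annotated genome plus a truth record of everything planted."""
    rng = np.random.default_rng(spec.seed)
    plan = _gene_plan(spec)

    # coordinates around the circle
    pos = 1
    for item in plan:
        item["start"] = pos
        item["end"] = pos + item["length"] - 1
        pos = item["end"] + item["igs"] + 1
    L = plan[-1]["end"] + plan[-1]["igs"]
    by_name = {p["name"]: p for p in plan}

    p_whole = base_probs(spec.at_content, spec.at_skew, spec.gc_skew)
    if spec.cr_at_content is not None:
        p_cr = base_probs(spec.cr_at_content, spec.at_skew, spec.gc_skew)
        l_cr = spec.cr_length
        p_bg = (L * p_whole - l_cr * p_cr) / (L - l_cr)
        if (p_bg <= 0).any():
            raise ValueError("CR composition override infeasible at this genome size")
        p_bg /= p_bg.sum()
    else:
        p_cr = p_whole
        p_bg = p_whole

    joint_h, _ = codon_joint(p_bg, spec.wobble_weights)
    joint_l, _ = codon_joint(p_bg[::-1], spec.wobble_weights)  # complement target

    seq = np.full(L, -1, dtype=np.int16)

    # 1. plant overlap motifs (fixed before either partner gene is filled)
    truth_overlaps = {}
    for i, up in enumerate(plan):
        down = plan[(i + 1) % len(plan)]
        if up["igs"] >= 0:
            continue
        ov = -up["igs"]
        if ov >= min(up["length"], down["length"]):
            raise ValueError(
                f"infeasible plan: overlap {ov} not shorter than "
                f"{up['name']}/{down['name']}")
        motif = spec.overlap_motifs.get((up["name"], down["name"]))
        if motif is None:
            raise ValueError(f"no motif supplied for overlap "
                             f"{up['name']}/{down['name']}")
        if len(motif) != ov:
            raise ValueError(
                f"motif length {len(motif)} != planned overlap {ov} for "
                f"{up['name']}/{down['name']}")
        start = down["start"]
        seq[start - 1:start - 1 + ov] = [_CODE[b] for b in motif.upper()]
        truth_overlaps[f"{up['name']}-{down['name']}"] = {
            "length": ov, "motif": motif.upper()}

    # 2. fill features in circle order
    for item in plan:
        s, e = item["start"] - 1, item["end"]  # 0-based half open
        if item["kind"] == "PCG":
            n = item["length"]
            joint = joint_h if item["strand"] == "H" else joint_l
            coding = seq[s:e].copy()
            if item["strand"] == "L":
                coding = 3 - coding[::-1]
                coding[coding > 3] = -1  # -1 maps to 4 under complement
            start_codon = (item["start_codon"] or "ATG").upper()
            stop = (item["stop_codon"] or "TAA").upper()
            for k, b in enumerate(start_codon):
                want = _CODE[b]
                if coding[k] >= 0 and coding[k] != want:
                    raise ValueError(f"{item['name']}: start codon clashes "
                                     "with a planted motif")
                coding[k] = want
            for k, b in enumerate(stop):
                idx = n - len(stop) + k
                want = _CODE[b]
                if coding[idx] >= 0 and coding[idx] != want:
                    raise ValueError(f"{item['name']}: stop codon clashes "
                                     "with a planted motif")
                coding[idx] = want
            body_len = n - 3 - len(stop)
            n_codons, slack = divmod(body_len, 3)
            for c in range(n_codons):
                i0 = 3 + 3 * c
                tri = coding[i0:i0 + 3]
                if (tri >= 0).all():
                    if tuple(tri) in _STOP_IDX:
                        raise ValueError(
                            f"{item['name']}: planted bases force an "
                            "internal stop codon")
                    continue
                coding[i0:i0 + 3] = _sample_constrained_codon(rng, joint, tri)
            for k in range(3 + 3 * n_codons, 3 + body_len):  # slack bases
                if coding[k] < 0:
                    coding[k] = rng.choice(4, p=p_bg if item["strand"] == "H"
                                           else p_bg[::-1])
            if item["strand"] == "L":
                coding = 3 - coding[::-1]
            seq[s:e] = coding
        else:
            probs = p_cr if item["kind"] == "CR" else p_bg
            free = np.flatnonzero(seq[s:e] < 0)
            seq[s:e][free] = rng.choice(4, p=probs, size=free.size)

    # 3. spacers (whatever is still unset, e.g. intergenic nucleotides)
    free = np.flatnonzero(seq < 0)
    seq[free] = rng.choice(4, p=p_bg, size=free.size)

    # 4. pseudo-tRNA-Met spacer between tRNA-Gln and ND2 (parrotfish only)
    truth_psi = None
    if spec.template == "parrotfish":
        met = by_name["tRNA-Met"]
        gln = by_name["tRNA-Gln"]
        gap_start, gap_end = gln["end"] + 1, by_name["ND2"]["start"] - 1
        gap_len = gap_end - gap_start + 1
        if gap_len >= 30:
            src = seq[met["start"] - 1:met["end"]]
            psi = _mutate_copy(rng, src, gap_len, spec.psi_similarity)
            seq[gap_start - 1:gap_end] = psi
            truth_psi = {"source": "tRNA-Met", "start": gap_start,
                         "end": gap_end,
                         "target_similarity": spec.psi_similarity}

    # 5. CSB plants inside the control region
    from .csb import default_consensus_set
    consensi = default_consensus_set()
    cr = by_name["CR"]
    truth_csb = {}
    offset = int(0.45 * spec.cr_length)
    for block in spec.csb_blocks:
        cons = consensi[block]
        seq[cr["start"] - 1 + offset:cr["start"] - 1 + offset + len(cons)] = [
            _CODE[b] for b in cons]
        truth_csb[block] = {"start_in_cr": offset + 1,
                            "end_in_cr": offset + len(cons),
                            "sequence": cons}
        offset += len(cons) + 25

    features = [
        GeneFeature(p["name"], p["kind"], p["start"], p["end"], p["strand"],
                    start_codon=p["start_codon"], stop_codon=p["stop_codon"],
                    anticodon=p["anticodon"])
        for p in plan
    ]
    genome = MitoGenome(id=spec.genome_id, sequence=_decode(seq),
                        features=features)
    truth = {
        "seed": spec.seed,
        "template": spec.template,
        "genome_length": L,
        "gene_order": [(p["name"], p["strand"]) for p in plan],
        "overlaps": truth_overlaps,
        "psi_spacer": truth_psi,
        "csb": truth_csb,
        "starts": {p["name"]: p["start_codon"] for p in plan
                   if p["kind"] == "PCG"},
        "stops": {p["name"]: p["stop_codon"] for p in plan
                  if p["kind"] == "PCG"},
        "targets": {"at_content": spec.at_content, "at_skew": spec.at_skew,
                    "gc_skew": spec.gc_skew},
    }
    return genome, truth


# ---------------------------------------------------------------------------
# sequence evolution


@dataclass
class EvolSpec:
    """Recipe for evolving sequences along a simple tree."""

    seed: int
    n_taxa: int = 10
    tree: str = "star"                 # or "symmetric"
    d: float = 0.1                     # root-to-tip substitutions per site
    kappa: float = 2.0                 # transition/transversion rate ratio
    gamma_alpha: Optional[float] = None
    omega: Optional[float] = None      # for the codon model only

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.tree not in ("star", "symmetric"):
            raise ValueError("tree must be 'star' or 'symmetric'")


def _k2p_probs(d, kappa):
    """(p_same, p_transition, p_each_transversion), vectorised over d."""
    d = np.asarray(d, dtype=float)
    beta = 1.0 / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (kappa + 1.0) * beta * d)
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return 1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv


def expected_p_distance(d_pairwise: float, kappa: float = 2.0) -> float:
    """Expected proportion of mismatched sites at a given K2P divergence."""
    same, _, _ = _k2p_probs(d_pairwise, kappa)
    return float(1.0 - same)


_TS_PARTNER = np.array([2, 3, 0, 1])            # A<->G, C<->T
_TV_PARTNERS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


def _evolve_branch(rng, seq: np.ndarray, d, kappa) -> np.ndarray:
    """One K2P branch; d may be scalar or per-site (gamma rates folded in)."""
    p_same, p_ts, p_tv = _k2p_probs(d, kappa)
    r = rng.random(seq.size)
    out = seq.copy()
    ts = (r >= p_same) & (r < p_same + p_ts)
    tv1 = (r >= p_same + p_ts) & (r < p_same + p_ts + p_tv)
    tv2 = r >= p_same + p_ts + p_tv
    out[ts] = _TS_PARTNER[seq[ts]]
    out[tv1] = _TV_PARTNERS[seq[tv1], 0]
    out[tv2] = _TV_PARTNERS[seq[tv2], 1]
    return out


def evolve_sequences(root: str, spec: EvolSpec) -> dict[str, str]:
    """Evolve a root sequence into an alignment of ``n_taxa`` descendants.

    Star trees give expected pairwise divergence 2d; symmetric trees are
    balanced bifurcating (n_taxa must be a power of two) with the same
    root-to-tip depth d.  Optional gamma rate heterogeneity draws one rate
    multiplier per site, shared across branches.
    """
    rng = np.random.default_rng(spec.seed)
    seq0 = np.array([_CODE[b] for b in root.upper()], dtype=np.int64)
    rates = (rng.gamma(spec.gamma_alpha, 1.0 / spec.gamma_alpha, seq0.size)
             if spec.gamma_alpha else 1.0)
    if spec.tree == "star":
        tips = [_evolve_branch(rng, seq0, spec.d * rates, spec.kappa)
                for _ in range(spec.n_taxa)]
    else:
        depth = int(np.log2(spec.n_taxa))
        if 2 ** depth != spec.n_taxa:
            raise ValueError("symmetric tree needs n_taxa = power of two")
        edge = spec.d / depth
        level = [seq0]
        for _ in range(depth):
            level = [_evolve_branch(rng, s, edge * rates, spec.kappa)
                     for s in level for _ in range(2)]
        tips = level
    return {f"t{i + 1}": _decode(t) for i, t in enumerate(tips)}


def saturated_alignment(n_taxa: int, length: int, seed: int,
                        freqs: Sequence[float] = (0.25,) * 4) -> dict[str, str]:
    """Fully saturated alignment: every cell i.i.d. from the base frequencies."""
    rng = np.random.default_rng(seed)
    arr = rng.choice(4, p=np.asarray(freqs), size=(n_taxa, length))
    return {f"t{i + 1}": _decode(arr[i]) for i in range(n_taxa)}


# --- codon model -----------------------------------------------------------


def _codon_rate_matrix(omega: float, kappa: float = 1.0) -> np.ndarray:
    """60-state codon rate matrix, mean rate 1 under a uniform distribution."""
    from .codons import translate
    n = len(_SENSE)
    Q = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            diff = [k for k in range(3) if _SENSE[i][k] != _SENSE[j][k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            a, b = _SENSE[i][k], _SENSE[j][k]
            ts = {a, b} in ({"A", "G"}, {"C", "T"})
            rate = kappa if ts else 1.0
            if translate(_SENSE[i]) != translate(_SENSE[j]):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -np.mean(np.diag(Q))  # branch lengths in substitutions per codon
    return Q


def evolve_codons(root_codons: str, spec: EvolSpec) -> dict[str, str]:
    """Evolve a coding sequence under a codon model with selection strength
    omega on a star tree; stop codons are outside the state space so none
    can ever appear.  Branch lengths are in expected substitutions per
    codon at omega = spec.omega.
    """
    if spec.omega is None:
        raise ValueError("EvolSpec.omega is required for the codon model")
    rng = np.random.default_rng(spec.seed)
    codons = [root_codons[i:i + 3].upper()
              for i in range(0, len(root_codons), 3)]
    if any(c in STOP_CODONS for c in codons):
        raise ValueError("root sequence contains a stop codon")
    idx = {c: i for i, c in enumerate(_SENSE)}
    root = np.array([idx[c] for c in codons])
    Q = _codon_rate_matrix(spec.omega, spec.kappa)
    P = expm(Q * spec.d)
    P = np.clip(P, 0, None)
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    out = {}
    for t in range(spec.n_taxa):
        r = rng.random(root.size)
        states = (cum[root] < r[:, None]).sum(axis=1)
        out[f"t{t + 1}"] = "".join(_SENSE[s] for s in states)
    return out


# ---------------------------------------------------------------------------
# study-scale helper


def make_genome_family(
    spec: GenomeSpec,
    n_taxa: int,
    d_genes: float = 0.02,
    d_cr: Optional[float] = None,
    kappa: float = 2.0,
    omega: Optional[float] = 0.15,
) -> tuple[list[MitoGenome], dict]:
    """A comparative study set: one ancestor, descendants on a star tree.

    Positions outside the control region diverge neutrally (K2P) at
    root-to-tip depth ``d_genes``; the control region, the fast-evolving
    part of real mitogenomes, diverges at ``d_cr`` (default 10x the gene
    rate; large values drive it to saturation).  When ``omega`` is set,
    protein-coding genes are instead evolved codon-wise under selection of
    that strength (at matched divergence, 3*d_genes substitutions per
    codon), so per-gene dN/dS recovers purifying selection the way real
    mitogenomes show it.  Annotations are shared across the family, so
    per-gene alignments fall out by coordinate slicing.
    """
    root, truth = make_genome(spec)
    if d_cr is None:
        d_cr = 10 * d_genes
    cr = root.feature("CR")
    L = root.length
    cr_mask = np.zeros(L, dtype=bool)
    if cr.end >= cr.start:
        cr_mask[cr.start - 1:cr.end] = True
    else:
        cr_mask[cr.start - 1:] = True
        cr_mask[:cr.end] = True
    # conserved sequence blocks stay slow inside the hypervariable region,
    # as in real control regions
    for info in truth.get("csb", {}).values():
        s = cr.start - 1 + info["start_in_cr"] - 1
        cr_mask[s:s + len(info["sequence"])] = False
    d_per_site = np.where(cr_mask, d_cr, d_genes)
    rng = np.random.default_rng(spec.seed + 1)
    seq0 = np.array([_CODE[b] for b in root.sequence], dtype=np.int64)
    tips = [_evolve_branch(rng, seq0, d_per_site, kappa)
            for _ in range(n_taxa)]

    if omega is not None:
        # overlay codon-model evolution on the complete codons of each PCG
        idx = {c: i for i, c in enumerate(_SENSE)}
        Q = _codon_rate_matrix(omega, kappa)
        P = expm(Q * 3 * d_genes)
        P = np.clip(P, 0, None)
        P /= P.sum(axis=1, keepdims=True)
        cum = np.cumsum(P, axis=1)
        for feat in sorted(root.features_of_kind("PCG"),
                           key=lambda f: f.start):
            coding0 = seq0[feat.start - 1:feat.end]
            if feat.strand == "L":
                coding0 = 3 - coding0[::-1]
            n_codons = coding0.size // 3
            tris = coding0[:n_codons * 3].reshape(n_codons, 3)
            states, keep = [], []
            for j, tri in enumerate(tris):
                c = _decode(tri)
                if c in idx:  # terminal stop codons stay on the K2P track
                    states.append(idx[c])
                    keep.append(j)
            states = np.array(states)
            for tip in tips:
                r = rng.random(states.size)
                new = (cum[states] < r[:, None]).sum(axis=1)
                block = tip[feat.start - 1:feat.end]
                coding = (3 - block[::-1]) if feat.strand == "L" else block.copy()
                for j, s in zip(keep, new):
                    coding[3 * j:3 * j + 3] = _SENSE_BASES[s]
                if feat.strand == "L":
                    coding = 3 - coding[::-1]
                tip[feat.start - 1:feat.end] = coding

    genomes = [
        MitoGenome(id=f"{spec.genome_id}_{i + 1:02d}", sequence=_decode(tip),
                   features=[replace(f) for f in root.features])
        for i, tip in enumerate(tips)
    ]
    truth = dict(truth, n_taxa=n_taxa, d_genes=d_genes, d_cr=d_cr,
                 kappa=kappa, omega=omega)
    return genomes, truth
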