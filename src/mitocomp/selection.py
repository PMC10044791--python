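"""Pairwise dN/dS by the Nei-Gojobori counting method and sequence distances.

Synonymous (S) and nonsynonymous (N) site counts per codon come from the
fraction of the three possible single-base changes at each position that
preserve the amino acid, with changes to stop codons excluded from the
denominator (vertebrate mitochondrial code throughout).  Observed
differences between codon pairs are averaged over all minimal mutational
pathways that avoid stop codons.  Proportions pN = Nd/N and pS = Sd/S are
Jukes-Cantor corrected, d = -3/4 ln(1 - 4p/3), and omega = dN/dS.

Whole-sequence distances are the p-distance (mismatches over pairwise
complete sites) and the Kimura two-parameter distance
K2P = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q), with P and Q the transition
and transversion proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .codons import BASES, SENSE_CODONS, STOP_CODONS, translate

_PURINES = {"A", "G"}


@lru_cache(maxsize=None)
def ng_site_counts(codon: str) -> tuple[float, float]:
    """(nonsynonymous sites, synonymous sites) for one sense codon.

    Each position contributes the fraction of its possible single-base
    changes that are synonymous; mutants that create a stop codon are
    excluded from that position's denominator (the position still counts
    as one full site).
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon")
    aa = translate(codon)
    syn_sites = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if translate(mutant) == aa:
                syn += 1
        if valid:
            syn_sites += syn / valid
    return 3.0 - syn_sites, syn_sites


@lru_cache(maxsize=None)
def _pair_differences(a: str, b: str) -> Optional[tuple[float, float]]:
    """(nonsyn diffs, syn diffs) averaged over stop-free minimal pathways."""
    if a == b:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    results = []
    for order in permutations(diff_pos):
        cur = a
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((nd, sd))
    if not results:
        return None
    arr = np.array(results)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction; undefined (None) at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * np.log(1 - 4 * p / 3)


@dataclass
class RatePair:
    """Nei-Gojobori rates for one sequence pair."""

    id_a: str
    id_b: str
    n_codons: int
    N: float
    S: float
    Nd: float
    Sd: float

    @property
    def pN(self) -> Optional[float]:
        return self.Nd / self.N if self.N > 0 else None

    @property
    def pS(self) -> Optional[float]:
        return self.Sd / self.S if self.S > 0 else None

    @property
    def dN(self) -> Optional[float]:
        p = self.pN
        return None if p is None else jukes_cantor(p)

    @property
    def dS(self) -> Optional[float]:
        p = self.pS
        return None if p is None else jukes_cantor(p)

    @property
    def omega(self) -> Optional[float]:
        dn, ds = self.dN, self.dS
        if dn is None or ds is None or ds == 0:
            return None
        return dn / ds


def _codon_split(seq: str) -> list[str]:
    if len(seq) % 3:
        raise ValueError("coding sequence length must be a multiple of 3")
    return [seq[i:i + 3].upper() for i in range(0, len(seq), 3)]


def ng_pairwise(seq_a: str, seq_b: str,
                id_a: str = "a", id_b: str = "b") -> RatePair:
    """Nei-Gojobori comparison of two equal-length coding sequences.

    Codons with gaps/ambiguity in either sequence, stop codons, and codon
    pairs whose every mutational pathway passes through a stop are dropped
    pairwise.  Site counts N and S are averaged between the two sequences.
    """
    ca, cb = _codon_split(seq_a), _codon_split(seq_b)
    if len(ca) != len(cb):
        raise ValueError("sequences must contain the same number of codons")
    N = S = Nd = Sd = 0.0
    used = 0
    for x, y in zip(ca, cb):
        if set(x) - set(BASES) or set(y) - set(BASES):
            continue
        if x in STOP_CODONS or y in STOP_CODONS:
            continue
        diffs = _pair_differences(x, y)
        if diffs is None:
            continue
        nx, sx = ng_site_counts(x)
        ny, sy = ng_site_counts(y)
        N += (nx + ny) / 2
        S += (sx + sy) / 2
        Nd += diffs[0]
        Sd += diffs[1]
        used += 1
    return RatePair(id_a, id_b, used, N, S, Nd, Sd)


def gene_omega(seqs: Mapping[str, str]) -> dict:
    """Per-gene omega over all sequence pairs.

    omega = (mean pairwise dN) / (mean pairwise dS), the ratio of means
    rather than the mean of ratios, because per-pair ratios are unstable
    for short genes; pairs with undefined (saturated) rates are excluded
    and reported.
    """
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("omega needs at least two sequences")
    dns, dss = [], []
    n_pairs = excluded = 0
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            rp = ng_pairwise(seqs[ids[i]], seqs[ids[j]], ids[i], ids[j])
            dn, ds = rp.dN, rp.dS
            if dn is None or ds is None:
                excluded += 1
                continue
            dns.append(dn)
            dss.append(ds)
            n_pairs += 1
    mean_dn = float(np.mean(dns)) if dns else float("nan")
    mean_ds = float(np.mean(dss)) if dss else float("nan")
    if not dss or mean_ds == 0:
        omega = None
    else:
        omega = mean_dn / mean_ds
    return {
        "n_taxa": len(ids), "n_pairs": n_pairs, "excluded_pairs": excluded,
        "mean_dN": mean_dn, "mean_dS": mean_ds, "omega": omega,
        "selection": (None if omega is None
                      else "purifying" if omega < 1
                      else "positive" if omega > 1 else "neutral"),
    }


def omega_table(gene_alignments: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    rows = []
    for gene in sorted(gene_alignments):
        res = gene_omega(gene_alignments[gene])
        rows.append({"gene": gene, **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-sequence distances


@dataclass
class DistanceMatrix:
    ids: list[str]
    p: np.ndarray
    k2p: np.ndarray

    def to_dataframe(self, which: str = "k2p") -> pd.DataFrame:
        m = self.k2p if which == "k2p" else self.p
        return pd.DataFrame(m, index=self.ids, columns=self.ids)

    def to_phylip(self, which: str = "k2p") -> str:
        m = self.k2p if which == "k2p" else self.p
        lines = [f"{len(self.ids)}"]
        for i, name in enumerate(self.ids):
            vals = " ".join(f"{v:.6f}" for v in m[i])
            lines.append(f"{name:<12s} {vals}")
        return "\n".join(lines) + "\n"


def _pq_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(compared sites, transitions, transversions) with pairwise deletion."""
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    diff = ok & (a != b)
    # codes: A=0 C=1 G=2 T=3; transitions are A<->G (0,2) and C<->T (1,3)
    ts = diff & (((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
                 | ((a == 1) & (b == 3)) | ((a == 3) & (b == 1)))
    return n, int(ts.sum()), int(diff.sum() - ts.sum())


def k2p_from_pq(P: float, Q: float) -> float:
    """Closed-form Kimura two-parameter distance; NaN out of domain."""
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return float("nan")
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def distances(alignment: Mapping[str, str] | Sequence[tuple[str, str]]) -> DistanceMatrix:
    """p-distance and K2P matrices over an aligned sequence set."""
    items = (list(alignment.items()) if isinstance(alignment, Mapping)
             else list(alignment))
    ids = [name for name, _ in items]
    from .saturation import _encode
    arr = _encode([s for _, s in items]) if len(items) >= 4 else None
    if arr is None:
        # small sets bypass the >=4 guard used by the saturation module
        L = len(items[0][1])
        arr = np.full((len(items), L), -1, dtype=np.int8)
        lut = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, (_, s) in enumerate(items):
            for j, ch in enumerate(s.upper()):
                arr[i, j] = lut.get(ch, -1)
    k = len(ids)
    pmat = np.zeros((k, k))
    kmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            n, ts, tv = _pq_counts(arr[i], arr[j])
            if n == 0:
                pmat[i, j] = pmat[j, i] = float("nan")
                kmat[i, j] = kmat[j, i] = float("nan")
                continue
            pmat[i, j] = pmat[j, i] = (ts + tv) / n
            kmat[i, j] = kmat[j, i] = k2p_from_pq(ts / n, tv / n)
    return DistanceMatrix(ids, pmat, kmat)
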