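"""Entropy-based substitution-saturation test for alignments.

The index Iss is the mean per-site Shannon entropy of an alignment divided
by the entropy expected under full saturation, i.e. when every column is
an independent multinomial draw of ``n_taxa`` bases from the alignment's
global base frequencies.  Iss near 0 means sites are still conserved; Iss
near 1 means site patterns are indistinguishable from random draws and the
alignment carries little phylogenetic signal.

The critical value Iss.c is the Iss level at which tree reconstruction
starts to fail.  It depends on the number of taxa, the alignment length
and the tree shape (symmetric vs asymmetric); a calibration table packaged
with this module (derived by simulation: K2P evolution over a grid of
depths, neighbour-joining reconstruction, 95% bipartition-recovery
threshold) is interpolated on log alignment length.  An alignment is
judged saturated when Iss >= Iss.c and a one-sample t-test of the per-site
entropy ratios against Iss.c is significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

TABLE_NTAXA = (4, 8, 16, 32)


def _encode(seqs: Sequence[str]) -> np.ndarray:
    """Alignment to int codes; non-ACGT becomes -1 (treated as missing)."""
    if len(seqs) < 4:
        raise ValueError("saturation statistics need at least 4 sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned (equal length)")
    arr = np.full((len(seqs), L), -1, dtype=np.int8)
    for i, s in enumerate(seqs):
        su = s.upper()
        for b, code in _BASE_INDEX.items():
            arr[i, np.frombuffer(su.encode(), dtype=np.uint8) ==
                ord(b)] = code
    return arr


def clean_alignment(seqs: Sequence[str], max_missing: float = 0.5) -> np.ndarray:
    """Encode and drop columns with more than ``max_missing`` gaps/ambiguity."""
    arr = _encode(seqs)
    missing_frac = (arr < 0).mean(axis=0)
    arr = arr[:, missing_frac <= max_missing]
    if arr.shape[1] == 0:
        raise ValueError("no usable columns after cleaning")
    return arr


def _column_counts(arr: np.ndarray) -> np.ndarray:
    """(L, 4) base counts per column, ignoring missing values."""
    L = arr.shape[1]
    counts = np.zeros((L, 4), dtype=np.int64)
    for b in range(4):
        counts[:, b] = (arr == b).sum(axis=0)
    return counts


def site_entropy_profile(seqs: Sequence[str] | np.ndarray) -> np.ndarray:
    """Per-site Shannon entropy (bits) over observed A/C/G/T at each column."""
    arr = seqs if isinstance(seqs, np.ndarray) else clean_alignment(seqs)
    counts = _column_counts(arr)
    n = counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, counts / n, 0.0)
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
    return h


def global_base_frequencies(arr: np.ndarray) -> np.ndarray:
    counts = np.array([(arr == b).sum() for b in range(4)], dtype=float)
    if counts.sum() == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return counts / counts.sum()


def _entropy_of_counts(k: np.ndarray) -> float:
    n = k.sum()
    p = k[k > 0] / n
    return float(-(p * np.log2(p)).sum())


@lru_cache(maxsize=128)
def _compositions(n: int) -> tuple[tuple[int, int, int, int], ...]:
    out = []
    for a in range(n + 1):
        for c in range(n - a + 1):
            for g in range(n - a - c + 1):
                out.append((a, c, g, n - a - c - g))
    return tuple(out)


def expected_entropy_full_saturation(
    n_taxa: int,
    freqs: Sequence[float],
    seed: int = 0,
    n_draws: int = 100_000,
) -> float:
    """E[column entropy] when columns are multinomial draws from ``freqs``.

    Exact enumeration of base compositions for n_taxa <= 12; seeded Monte
    Carlo (``n_draws`` multinomial draws) beyond that.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= 1.0 - 1e-12:
        raise ValueError("expected entropy undefined for a single-base alignment")
    if n_taxa <= 12:
        total = 0.0
        for comp in _compositions(n_taxa):
            k = np.array(comp)
            logp = (sps.multinomial.logpmf(k, n_taxa, freqs)
                    if freqs.min() > 0 else _safe_logpmf(k, n_taxa, freqs))
            if np.isfinite(logp):
                total += np.exp(logp) * _entropy_of_counts(k)
        return total
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_taxa, freqs, size=n_draws)
    n = float(n_taxa)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = draws / n
        h = np.where(p > 0, -p * np.log2(p), 0.0).sum(axis=1)
    return float(h.mean())


def _safe_logpmf(k: np.ndarray, n: int, p: np.ndarray) -> float:
    if np.any((p == 0) & (k > 0)):
        return -np.inf
    mask = p > 0
    from scipy.special import gammaln
    return float(gammaln(n + 1) - gammaln(k[mask] + 1).sum()
                 + (k[mask] * np.log(p[mask])).sum())


def iss(seqs: Sequence[str] | np.ndarray, seed: int = 0) -> float:
    """Saturation index: mean site entropy / full-saturation expectation."""
    arr = seqs if isinstance(seqs, np.ndarray) else clean_alignment(seqs)
    h = site_entropy_profile(arr)
    h_fss = expected_entropy_full_saturation(
        arr.shape[0], global_base_frequencies(arr), seed=seed)
    return float(h.mean() / h_fss)


# ---------------------------------------------------------------------------
# critical values


@lru_cache(maxsize=1)
def _critical_table() -> pd.DataFrame:
    with resources.as_file(
            resources.files("mitocomp.data") / "iss_critical.tsv") as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return df


def iss_critical(n_taxa: int, length: int,
                 topology: str = "symmetric") -> float:
    """Critical Iss for a given taxon count, alignment length and tree shape.

    Values are linearly interpolated on log(length) within the packaged
    calibration table (and beyond its length range, linearly extrapolated,
    which preserves monotonicity in length).  Taxon counts between table
    rows are interpolated on log2(n_taxa); counts above 32 use the
    32-taxon row, which is how the subsampling rule in
    :func:`saturation_test` expects to be paired.
    """
    if topology not in ("symmetric", "asymmetric"):
        raise ValueError("topology must be 'symmetric' or 'asymmetric'")
    if n_taxa < 4:
        raise ValueError("critical values require at least 4 taxa")
    df = _critical_table()
    df = df[df["topology"] == topology]
    lengths = np.sort(df["length"].unique())
    if length < lengths.min():
        raise ValueError(
            f"alignment length {length} below calibrated range "
            f"(min {lengths.min()})")

    def row_value(nt: int) -> float:
        sub = df[df["n_taxa"] == nt].sort_values("length")
        x = np.log(sub["length"].to_numpy(dtype=float))
        y = sub["iss_c"].to_numpy(dtype=float)
        lx = np.log(length)
        if lx >= x[-1]:  # linear extrapolation on log length
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            return float(y[-1] + slope * (lx - x[-1]))
        return float(np.interp(lx, x, y))

    nt = min(n_taxa, 32)
    if nt in TABLE_NTAXA:
        return row_value(nt)
    lo = max(t for t in TABLE_NTAXA if t < nt)
    hi = min(t for t in TABLE_NTAXA if t > nt)
    w = (np.log2(nt) - np.log2(lo)) / (np.log2(hi) - np.log2(lo))
    return float((1 - w) * row_value(lo) + w * row_value(hi))


# ---------------------------------------------------------------------------
# the test


@dataclass
class SaturationResult:
    """Outcome of the Iss-vs-Iss.c comparison for one alignment."""

    n_taxa: int
    n_sites: int
    iss: float
    iss_c: float
    t_statistic: float
    p_value: float
    verdict: str  # unsaturated / saturated / inconclusive
    topology: str
    subsampled: bool = False
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa, "n_sites": self.n_sites,
            "iss": self.iss, "iss_c": self.iss_c,
            "t_statistic": self.t_statistic, "p_value": self.p_value,
            "verdict": self.verdict, "topology": self.topology,
            "subsampled": self.subsampled, "seed": self.seed,
        }


def saturation_test(
    seqs: Sequence[str],
    topology: str = "symmetric",
    alpha: float = 0.05,
    seed: int = 0,
    n_subsamples: int = 30,
) -> SaturationResult:
    """Test an alignment for substitution saturation.

    Sequences have not experienced saturation when Iss is significantly
    below Iss.c; they are reported saturated when Iss >= Iss.c with the
    t-test significant, and inconclusive otherwise (including degenerate
    per-site variance).  For more than 32 taxa, Iss is averaged over
    ``n_subsamples`` seeded random 32-taxon subsamples and compared with
    the 32-taxon critical value.
    """
    arr = clean_alignment(seqs)
    n_taxa, L = arr.shape
    subsampled = False
    if n_taxa > 32:
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_subsamples):
            idx = rng.choice(n_taxa, 32, replace=False)
            vals.append(iss(arr[idx], seed=seed))
        iss_val = float(np.mean(vals))
        h_fss = expected_entropy_full_saturation(
            32, global_base_frequencies(arr), seed=seed)
        # per-site ratios from the full profile, scaled to the subsample mean
        ratios = site_entropy_profile(arr) / site_entropy_profile(arr).mean() * iss_val
        crit = iss_critical(32, L, topology)
        subsampled = True
    else:
        h = site_entropy_profile(arr)
        h_fss = expected_entropy_full_saturation(
            n_taxa, global_base_frequencies(arr), seed=seed)
        ratios = h / h_fss
        iss_val = float(ratios.mean())
        crit = iss_critical(n_taxa, L, topology)

    if np.allclose(ratios.std(ddof=1), 0.0):
        return SaturationResult(n_taxa, L, iss_val, crit, float("nan"),
                                float("nan"),
                                "unsaturated" if iss_val < crit else "inconclusive",
                                topology, subsampled, seed)
    t_stat, p = sps.ttest_1samp(ratios, popmean=crit)
    if p < alpha:
        verdict = "saturated" if iss_val >= crit else "unsaturated"
    else:
        verdict = "inconclusive"
    return SaturationResult(n_taxa, L, iss_val, crit, float(t_stat), float(p),
                            verdict, topology, subsampled, seed)
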