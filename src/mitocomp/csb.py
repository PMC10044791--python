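"""Conserved-sequence-block (CSB) scanning in control regions.

Vertebrate control regions carry short conserved blocks (CSB-D, CSB-I,
CSB-II, CSB-III) involved in replication and transcription.  The scanner
slides each consensus along the control region and reports the
best-scoring placement (leftmost on ties), where the score is the
fraction of consensus positions matched, IUPAC-aware.  Blocks scoring
below the threshold are reported absent — e.g. CSB-III in parrotfish-like
control regions.

The packaged consensus set is a synthetic default modelled on the
composition of teleost CSBs (the authoritative strings vary by lineage);
it is a plain FASTA users can replace with their own consensi.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values

BLOCK_ORDER = ("CSB-D", "CSB-I", "CSB-II", "CSB-III")

_IUPAC = {k.upper(): set(v.upper()) for k, v in ambiguous_dna_values.items()}


@lru_cache(maxsize=1)
def default_consensus_set() -> dict[str, str]:
    with resources.as_file(
            resources.files("mitocomp.data") / "csb_consensus.fasta") as p:
        return load_consensus_set(p)


def load_consensus_set(path: str | Path) -> dict[str, str]:
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        block = rec.id.split()[0]
        out[block] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"{path}: empty consensus set")
    return out


@dataclass
class CSBHit:
    """One located block within a control region (1-based CR coordinates)."""

    block: str
    start: int
    end: int
    sequence: str
    score: float


def _match(base: str, consensus: str) -> bool:
    return base in _IUPAC.get(consensus, {consensus})


def _scan_one(cr: str, consensus: str) -> tuple[int, float]:
    """(best 0-based offset, best score); leftmost placement on ties."""
    m = len(consensus)
    best_off, best_score = 0, -1.0
    for off in range(len(cr) - m + 1):
        window = cr[off:off + m]
        score = sum(_match(b, c) for b, c in zip(window, consensus)) / m
        if score > best_score:
            best_off, best_score = off, score
    return best_off, best_score


def scan_csb(
    cr_sequence: str,
    consensus_set: Optional[Mapping[str, str]] = None,
    min_score: float = 0.8,
) -> list[CSBHit]:
    """Locate CSBs in a control-region sequence.

    Returns hits in CR coordinate order; overlapping placements are
    resolved in favour of the higher-scoring block, the loser taking its
    best non-overlapping placement (dropped if that falls below
    ``min_score``).
    """
    cr = cr_sequence.upper()
    consensi = (dict(consensus_set) if consensus_set is not None
                else default_consensus_set())
    if not consensi:
        raise ValueError("empty consensus set")
    longest = max(len(s) for s in consensi.values())
    if len(cr) < longest:
        raise ValueError("control region shorter than the longest consensus")

    provisional: list[CSBHit] = []
    for block in sorted(consensi, key=lambda b: (
            BLOCK_ORDER.index(b) if b in BLOCK_ORDER else len(BLOCK_ORDER))):
        cons = consensi[block]
        off, score = _scan_one(cr, cons)
        if score >= min_score:
            provisional.append(CSBHit(block, off + 1, off + len(cons),
                                      cr[off:off + len(cons)], score))

    accepted: list[CSBHit] = []
    for hit in sorted(provisional, key=lambda h: (-h.score, h.start)):
        if all(hit.end < a.start or hit.start > a.end for a in accepted):
            accepted.append(hit)
            continue
        # relocate to the best non-overlapping window
        cons = consensi[hit.block]
        m = len(cons)
        best = None
        for off in range(len(cr) - m + 1):
            s, e = off + 1, off + m
            if any(not (e < a.start or s > a.end) for a in accepted):
                continue
            score = sum(_match(b, c) for b, c in zip(cr[off:off + m], cons)) / m
            if best is None or score > best[1]:
                best = (off, score)
        if best and best[1] >= min_score:
            off, score = best
            accepted.append(CSBHit(hit.block, off + 1, off + m,
                                   cr[off:off + m], score))
    return sorted(accepted, key=lambda h: h.start)


def scan_genomes(genomes: Iterable, consensus_set=None,
                 min_score: float = 0.8) -> pd.DataFrame:
    """CSB hit table across genomes (one row per located block)."""
    rows = []
    for g in genomes:
        cr_feats = [f for f in g.features if f.kind == "CR"]
        if not cr_feats or not g.has_sequence:
            continue
        cr = g.extract(cr_feats[0])
        for hit in scan_csb(cr, consensus_set, min_score):
            rows.append({"genome_id": g.id, "block": hit.block,
                         "start": hit.start, "end": hit.end,
                         "sequence": hit.sequence, "score": hit.score})
    return pd.DataFrame(rows, columns=["genome_id", "block", "start", "end",
                                       "sequence", "score"])


def block_composition(hits: pd.DataFrame | Iterable[CSBHit]) -> pd.DataFrame:
    """Pooled base percentages per block across genomes (rows sum to 100)."""
    if isinstance(hits, pd.DataFrame):
        seqs_by_block: dict[str, list[str]] = {}
        for _, row in hits.iterrows():
            seqs_by_block.setdefault(row["block"], []).append(row["sequence"])
    else:
        seqs_by_block = {}
        for h in hits:
            seqs_by_block.setdefault(h.block, []).append(h.sequence)
    rows = []
    for block in sorted(seqs_by_block):
        pooled = "".join(seqs_by_block[block]).upper()
        counts = {b: pooled.count(b) for b in "ACGT"}
        total = sum(counts.values())
        if total == 0:
            continue
        rows.append({"block": block,
                     **{b: 100.0 * counts[b] / total for b in "ACGT"}})
    return pd.DataFrame(rows, columns=["block", "A", "C", "G", "T"])
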