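"""Orchestration of the comparative-mitogenomics workflow.

Runs the analysis stages over a set of annotated genomes and emits one
TSV per table plus a JSON summary: genome organization (37-gene
completeness, strand tallies), per-partition composition and skew, codon
calls and RSCU, adjacency/overlap/spacer accounting and rearrangement
against a reference order, control-region CSB hits, substitution
saturation per partition (saturated partitions are flagged as excluded
from phylogenetic use, the conventional gate), per-gene dN/dS, and
pairwise distances.

Sequence-dependent stages are skipped with a notice for genomes that
carry only a feature table; per-genome failures are isolated into a
failure manifest so one bad record does not abort a comparative run.
"""

from __future__ import annotations

import traceback
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from . import architecture, composition, csb, saturation, selection
from . import codons as codon_mod
from .io import MitoGenome, read_feature_table, read_genbank, write_reports

ALL_STAGES = ("organization", "composition", "codons", "architecture",
              "csb", "saturation", "dnds", "distance")


@dataclass
class RunConfig:
    """Configuration for one pipeline run; CLI flags override file values."""

    inputs: list[str] = field(default_factory=list)
    out_dir: Optional[str] = None
    stages: tuple[str, ...] = ALL_STAGES
    genetic_code: int = 2
    alpha: float = 0.05
    topology: str = "symmetric"
    reference_order: str = "vertebrate"   # vertebrate | parrotfish | <file>
    min_csb_score: float = 0.8
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.genetic_code != 2:
            raise ValueError("only the vertebrate mitochondrial code (2) "
                             "is supported")
        for p in self.inputs:
            if not Path(p).exists():
                raise FileNotFoundError(p)


def load_genomes(inputs: Sequence[str | Path]) -> list[MitoGenome]:
    """Load genomes from GenBank files, TSV(+FASTA) pairs, or directories."""
    paths: list[Path] = []
    for item in inputs:
        p = Path(item)
        if p.is_dir():
            paths.extend(sorted(p.iterdir()))
        else:
            paths.append(p)
    if not paths:
        raise ValueError("no input files found")
    genomes = []
    seen_tsv = set()
    for p in paths:
        if p.suffix in (".gb", ".gbk", ".genbank"):
            genomes.append(read_genbank(p))
        elif p.suffix == ".tsv" and p not in seen_tsv:
            fasta = None
            for ext in (".fasta", ".fa", ".fna"):
                cand = p.with_suffix(ext)
                if cand.exists():
                    fasta = cand
                    break
            genomes.append(read_feature_table(p, fasta=fasta))
            seen_tsv.add(p)
    if not genomes:
        raise ValueError("no mitogenome inputs recognised "
                         "(expect .gb/.gbk or .tsv with optional .fasta)")
    return genomes


def _reference_order(name: str):
    if name == "vertebrate":
        return architecture.CANONICAL_VERTEBRATE_ORDER
    if name == "parrotfish":
        return architecture.PARROTFISH_ORDER
    genome = read_feature_table(name)
    return architecture.GeneOrder.from_genome(genome).genes


def gene_alignments(genomes: Sequence[MitoGenome]) -> dict[str, dict[str, str]]:
    """Per-PCG coding-strand pseudo-alignments (genes of equal length only).

    Genomes from a shared annotation (e.g. a simulated family) align by
    coordinates; externally aligned per-gene FASTA input is handled by the
    selection module directly.
    """
    out: dict[str, dict[str, str]] = {}
    with_seq = [g for g in genomes if g.has_sequence]
    if not with_seq:
        return out
    names = set.intersection(*(
        {f.name for f in g.features_of_kind("PCG")} for g in with_seq))
    for name in sorted(names):
        seqs = {g.id: g.extract(name) for g in with_seq}
        if len({len(s) for s in seqs.values()}) == 1:
            # trim the truncated terminal codon so codon arithmetic is exact
            n3 = (len(next(iter(seqs.values()))) // 3) * 3
            out[name] = {k: s[:n3] for k, s in seqs.items()}
    return out


def partition_alignments(genomes: Sequence[MitoGenome]) -> dict[str, dict[str, str]]:
    """Equal-length partition stacks (CR, PCG concat, rRNA concat, ...)."""
    stacks: dict[str, dict[str, str]] = {}
    for g in genomes:
        if not g.has_sequence:
            continue
        for p in composition.build_partitions(g):
            stacks.setdefault(p.name, {})[g.id] = p.sequence
    n = len([g for g in genomes if g.has_sequence])
    return {name: seqs for name, seqs in stacks.items()
            if len(seqs) == n and len({len(s) for s in seqs.values()}) == 1}


def run_pipeline(
    genomes: Sequence[MitoGenome],
    config: Optional[RunConfig] = None,
) -> dict:
    """Run the configured stages and return {table name: DataFrame | dict}.

    Pass the result to :func:`mitocomp.io.write_reports` (done
    automatically when ``config.out_dir`` is set) for on-disk TSV/JSON
    output with deterministic ordering.
    """
    cfg = config or RunConfig()
    genomes = sorted(genomes, key=lambda g: g.id)
    if not genomes:
        raise ValueError("no genomes supplied")
    with_seq = [g for g in genomes if g.has_sequence]
    results: dict = {}
    notices: list[str] = []
    failures: list[dict] = []

    def attempt(stage: str, fn) -> None:
        if stage not in cfg.stages:
            return
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fn()
            msgs = sorted({str(w.message) for w in caught})
            if msgs:
                notices.append(f"{stage}: {len(msgs)} warning(s), e.g. "
                               + "; ".join(msgs[:3]))
        except Exception as exc:  # isolate stage/genome failures
            failures.append({"stage": stage, "error": str(exc),
                             "trace": traceback.format_exc(limit=3)})

    if len(with_seq) < len(genomes):
        notices.append(
            f"{len(genomes) - len(with_seq)} genome(s) lack sequence: "
            "sequence-dependent stages cover the remainder only")

    # organization ---------------------------------------------------------
    def _organization():
        rows = []
        for g in genomes:
            rep = g.completeness_report()
            rows.append({"genome_id": g.id, "length": g.length, **rep})
        results["organization"] = pd.DataFrame(rows)
    attempt("organization", _organization)

    # composition ----------------------------------------------------------
    def _composition():
        if not with_seq:
            notices.append("composition skipped: no sequences")
            return
        results["composition"] = composition.composition_table(with_seq)
    attempt("composition", _composition)

    # codons ---------------------------------------------------------------
    def _codons():
        calls = []
        for g in genomes:
            for feat in g.features_of_kind("PCG"):
                if not g.has_sequence and not (feat.start_codon or feat.stop_codon):
                    continue
                c = codon_mod.call_gene(g, feat.name)
                calls.append({"genome_id": g.id, "gene": c.gene,
                              "start_codon": c.start_codon,
                              "start_class": c.start_class,
                              "stop_codon": c.stop_codon,
                              "stop_class": c.stop_class})
        results["codon_calls"] = pd.DataFrame(calls)
        if with_seq:
            per_genome, pooled = codon_mod.codon_usage_counts(with_seq)
            results["rscu_pooled"] = codon_mod.rscu(pooled)
            per_rows = []
            for gid in sorted(per_genome):
                df = codon_mod.rscu(per_genome[gid])
                df.insert(0, "genome_id", gid)
                per_rows.append(df)
            results["rscu_per_genome"] = pd.concat(per_rows, ignore_index=True)
            results["amino_acid_frequencies"] = \
                codon_mod.amino_acid_frequencies(pooled)
    attempt("codons", _codons)

    # architecture ---------------------------------------------------------
    def _architecture():
        results["adjacency"] = architecture.adjacency_dataframe(genomes)
        book = [architecture.circular_bookkeeping(g) for g in genomes]
        results["bookkeeping"] = pd.DataFrame(book)
        ref = _reference_order(cfg.reference_order)
        rows = []
        for g in genomes:
            order = architecture.GeneOrder.from_genome(g)
            rows.append({
                "genome_id": g.id,
                "order": str(order),
                "breakpoints_vs_reference":
                    architecture.breakpoint_distance(order, ref),
                "displaced_genes": ",".join(sorted(
                    architecture.find_displaced_genes(order, ref))),
            })
        results["gene_order"] = pd.DataFrame(rows)
        if with_seq:
            psi = [architecture.pseudogene_candidates(g) for g in with_seq]
            results["pseudogene_candidates"] = pd.concat(psi, ignore_index=True)
            for pair in (("ATP8", "ATP6"), ("ND4L", "ND4"), ("ND5", "ND6")):
                df = architecture.overlap_motifs(with_seq, pair)
                if not df.empty:
                    df.insert(1, "pair", f"{pair[0]}/{pair[1]}")
                    results.setdefault("_motifs", []).append(df)
            if "_motifs" in results:
                results["overlap_motifs"] = pd.concat(
                    results.pop("_motifs"), ignore_index=True)
    attempt("architecture", _architecture)

    # csb ------------------------------------------------------------------
    def _csb():
        if not with_seq:
            notices.append("csb skipped: no sequences")
            return
        hits = csb.scan_genomes(with_seq, min_score=cfg.min_csb_score)
        results["csb_hits"] = hits
        if not hits.empty:
            results["csb_composition"] = csb.block_composition(hits)
    attempt("csb", _csb)

    # saturation -----------------------------------------------------------
    def _saturation():
        stacks = partition_alignments(genomes)
        rows = []
        for name in sorted(stacks):
            seqs = [stacks[name][k] for k in sorted(stacks[name])]
            if len(seqs) < 4:
                continue
            res = saturation.saturation_test(
                seqs, topology=cfg.topology, alpha=cfg.alpha, seed=cfg.seed)
            rows.append({"partition": name, **res.to_dict(),
                         "excluded_from_phylogenetic_use":
                             res.verdict == "saturated"})
        if not rows:
            notices.append("saturation skipped: fewer than 4 comparable "
                           "sequences per partition")
            return
        results["saturation"] = pd.DataFrame(rows)
    attempt("saturation", _saturation)

    # dnds -----------------------------------------------------------------
    def _dnds():
        aligns = gene_alignments(genomes)
        if not aligns:
            notices.append("dnds skipped: no comparable coding sequences")
            return
        results["omega"] = selection.omega_table(aligns)
    attempt("dnds", _dnds)

    # distance -------------------------------------------------------------
    def _distance():
        usable = [g for g in with_seq]
        if len(usable) < 2 or len({g.length for g in usable}) != 1:
            notices.append("distance skipped: need >=2 equal-length sequences")
            return
        dm = selection.distances({g.id: g.sequence for g in usable})
        results["distance_p"] = dm.to_dataframe("p").reset_index(
            names="genome_id")
        results["distance_k2p"] = dm.to_dataframe("k2p").reset_index(
            names="genome_id")
    attempt("distance", _distance)

    # summary --------------------------------------------------------------
    summary = {
        "n_genomes": len(genomes),
        "genome_ids": [g.id for g in genomes],
        "stages_run": [s for s in cfg.stages if s in results
                       or s in ("codons", "architecture", "distance")],
        "settings": {
            "genetic_code": cfg.genetic_code,
            "saturation_alpha": cfg.alpha,
            "saturation_topology": cfg.topology,
            "reference_order": cfg.reference_order,
            "min_csb_score": cfg.min_csb_score,
            "omega_aggregation": "ratio of mean pairwise dN to mean pairwise dS",
            "multiple_testing_correction": "none (per-partition tests reported raw)",
            "seed": cfg.seed,
        },
        "notices": notices,
        "failures": failures,
    }
    if "organization" in results:
        summary["complete_37"] = {
            r["genome_id"]: bool(r["complete_37"])
            for _, r in results["organization"].iterrows()}
    if "saturation" in results:
        summary["excluded_from_phylogenetic_use"] = [
            r["partition"] for _, r in results["saturation"].iterrows()
            if r["excluded_from_phylogenetic_use"]]
    results["run_summary"] = summary

    if cfg.out_dir:
        write_reports(results, cfg.out_dir)
    return results
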