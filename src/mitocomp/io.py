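"""Reading and writing annotated mitochondrial genomes.

A mitogenome is represented as a circular nucleotide sequence plus an
ordered list of features (protein-coding genes, tRNAs, rRNAs, the control
region).  Coordinates are 1-based and inclusive at every public interface,
matching the convention of published mitogenome feature tables; a feature
may wrap the origin of the circle (``end < start``).

Two input routes are supported: GenBank flat files (via Biopython) and a
plain TSV feature table, optionally paired with a FASTA sequence.  Feature
names are normalised to canonical labels (``ND5``, ``COI``, ``tRNA-Met``,
``CR`` ...) through a synonym table so that downstream comparisons across
annotation pipelines line up.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

KINDS = ("PCG", "tRNA", "rRNA", "CR", "pseudogene", "OL")

#: amino-acid one/three letter forms used to canonicalise tRNA labels
_AA3 = {
    "ala": "Ala", "arg": "Arg", "asn": "Asn", "asp": "Asp", "cys": "Cys",
    "gln": "Gln", "glu": "Glu", "gly": "Gly", "his": "His", "ile": "Ile",
    "leu": "Leu", "lys": "Lys", "met": "Met", "phe": "Phe", "pro": "Pro",
    "ser": "Ser", "thr": "Thr", "trp": "Trp", "tyr": "Tyr", "val": "Val",
}

# Synonyms seen across MITOS / MitoAnnotator / GenBank deposits.
SYNONYMS = {
    "atp8": "ATP8", "atpase8": "ATP8", "atpase 8": "ATP8",
    "atp synthase f0 subunit 8": "ATP8", "atp synthase 8": "ATP8",
    "atp6": "ATP6", "atpase6": "ATP6", "atpase 6": "ATP6",
    "atp synthase f0 subunit 6": "ATP6", "atp synthase 6": "ATP6",
    "cox1": "COI", "coxi": "COI", "co1": "COI", "coi": "COI",
    "cytochrome c oxidase subunit 1": "COI",
    "cytochrome c oxidase subunit i": "COI",
    "cox2": "COII", "coxii": "COII", "co2": "COII", "coii": "COII",
    "cytochrome c oxidase subunit 2": "COII",
    "cytochrome c oxidase subunit ii": "COII",
    "cox3": "COIII", "coxiii": "COIII", "co3": "COIII", "coiii": "COIII",
    "cytochrome c oxidase subunit 3": "COIII",
    "cytochrome c oxidase subunit iii": "COIII",
    "cob": "Cytb", "cytb": "Cytb", "cyt b": "Cytb", "cytochrome b": "Cytb",
    "nad1": "ND1", "nd1": "ND1", "nadh dehydrogenase subunit 1": "ND1",
    "nad2": "ND2", "nd2": "ND2", "nadh dehydrogenase subunit 2": "ND2",
    "nad3": "ND3", "nd3": "ND3", "nadh dehydrogenase subunit 3": "ND3",
    "nad4": "ND4", "nd4": "ND4", "nadh dehydrogenase subunit 4": "ND4",
    "nad4l": "ND4L", "nd4l": "ND4L", "nadh dehydrogenase subunit 4l": "ND4L",
    "nad5": "ND5", "nd5": "ND5", "nadh dehydrogenase subunit 5": "ND5",
    "nad6": "ND6", "nd6": "ND6", "nadh dehydrogenase subunit 6": "ND6",
    "d-loop": "CR", "dloop": "CR", "control region": "CR", "cr": "CR",
    "rrns": "12S-rRNA", "12s": "12S-rRNA", "12s rrna": "12S-rRNA",
    "12s-rrna": "12S-rRNA", "12s ribosomal rna": "12S-rRNA",
    "s-rrna": "12S-rRNA", "small subunit ribosomal rna": "12S-rRNA",
    "rrnl": "16S-rRNA", "16s": "16S-rRNA", "16s rrna": "16S-rRNA",
    "16s-rrna": "16S-rRNA", "16s ribosomal rna": "16S-rRNA",
    "l-rrna": "16S-rRNA", "large subunit ribosomal rna": "16S-rRNA",
    "ol": "OL", "l-strand origin": "OL",
    "origin of l-strand replication": "OL", "rep_origin": "OL",
}


def canonical_name(raw: str, anticodon: str | None = None) -> str:
    """Map an annotation label onto the canonical gene name.

    tRNA labels keep an anticodon suffix for the two-copy genes
    (``tRNA-Leu(UAA)`` vs ``tRNA-Leu(UAG)``, ``tRNA-Ser(UGA)`` vs
    ``tRNA-Ser(GCU)``) so the 22 tRNAs stay distinguishable.  Unmappable
    names are returned verbatim with a warning.
    """
    s = raw.strip()
    key = s.lower().replace("_", " ").strip()
    key = re.sub(r"\s+", " ", key)
    if key in SYNONYMS:
        return SYNONYMS[key]
    m = re.match(r"(?:trna[- ]?([a-z]{3})|trn([a-z])\d?$)\s*(?:\(([a-z]+)\))?", key)
    if m:
        if m.group(1) and m.group(1) in _AA3:
            aa = _AA3[m.group(1)]
        elif m.group(2):
            one_to_three = {
                "a": "Ala", "r": "Arg", "n": "Asn", "d": "Asp", "c": "Cys",
                "q": "Gln", "e": "Glu", "g": "Gly", "h": "His", "i": "Ile",
                "l": "Leu", "k": "Lys", "m": "Met", "f": "Phe", "p": "Pro",
                "s": "Ser", "t": "Thr", "w": "Trp", "y": "Tyr", "v": "Val",
            }
            aa = one_to_three.get(m.group(2), "")
        else:
            aa = ""
        if aa:
            ac = (m.group(3) or (anticodon or "")).upper().replace("U", "T")
            if aa in ("Leu", "Ser") and ac:
                # store suffix in RNA alphabet, the field convention
                return f"tRNA-{aa}({ac.replace('T', 'U')})"
            if aa in ("Leu", "Ser"):
                return f"tRNA-{aa}"
            return f"tRNA-{aa}"
    warnings.warn(f"unmappable feature name kept verbatim: {raw!r}")
    return s


def infer_kind(name: str) -> str:
    if name.startswith("tRNA"):
        return "tRNA"
    if "rRNA" in name:
        return "rRNA"
    if name == "CR":
        return "CR"
    if name == "OL":
        return "OL"
    return "PCG"


@dataclass
class GeneFeature:
    """One annotated feature on the circular genome (1-based inclusive)."""

    name: str
    kind: str
    start: int
    end: int
    strand: str = "H"
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    anticodon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be H or L, got {self.strand!r}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.start < 1:
            raise ValueError("start must be >= 1")

    def length(self, genome_length: Optional[int] = None) -> int:
        """Feature length in bp; wrap-around features need ``genome_length``."""
        if self.end >= self.start:
            return self.end - self.start + 1
        if genome_length is None:
            raise ValueError(f"{self.name}: end < start requires genome length")
        return genome_length - self.start + 1 + self.end

    @property
    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class MitoGenome:
    """A circular mitochondrial genome with ordered feature annotations."""

    id: str
    sequence: str = ""
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    length: Optional[int] = None  # needed when no sequence is attached
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: f.start)
        if self.sequence:
            self.length = len(self.sequence)
        elif self.length is None and self.features:
            self.length = max(f.end for f in self.features)

    @property
    def has_sequence(self) -> bool:
        return bool(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{self.id}: no feature named {name!r}")

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == kind]

    def region(self, start: int, end: int) -> str:
        """H-strand subsequence, 1-based inclusive, wrap-aware."""
        if not self.sequence:
            raise ValueError(f"{self.id}: genome carries no sequence")
        n = len(self.sequence)
        if not (1 <= start <= n):
            raise ValueError(f"start {start} outside [1, {n}]")
        if end >= start:
            return self.sequence[start - 1:end]
        return self.sequence[start - 1:] + self.sequence[:end]

    def extract(self, feat: GeneFeature | str) -> str:
        """Coding-strand sequence of a feature (L-strand reverse-complemented)."""
        if isinstance(feat, str):
            feat = self.feature(feat)
        s = self.region(feat.start, feat.end)
        if feat.strand == "L":
            s = str(Seq(s).reverse_complement())
        return s

    def completeness_report(self) -> dict:
        """Count the canonical 37-gene complement (report, never an error)."""
        kinds = {k: len(self.features_of_kind(k)) for k in ("PCG", "tRNA", "rRNA", "CR")}
        kinds["complete_37"] = (
            kinds["PCG"] == 13 and kinds["tRNA"] == 22 and kinds["rRNA"] == 2
        )
        kinds["l_strand_trnas"] = sum(
            1 for f in self.features_of_kind("tRNA") if f.strand == "L"
        )
        kinds["l_strand_pcgs"] = sum(
            1 for f in self.features_of_kind("PCG") if f.strand == "L"
        )
        return kinds


# ---------------------------------------------------------------------------
# readers


def read_genbank(path: str | Path) -> MitoGenome:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features are mapped to canonical names; coordinates
    are normalised to 1-based inclusive.  A record without sequence raises;
    a record without features parses to an empty feature list with a warning.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if not seq or set(seq) == {"N"} or len(seq) == 0:
        raise ValueError(f"{path}: GenBank record has no usable sequence")
    feats: list[GeneFeature] = []
    notes: list[str] = []
    for f in record.features:
        if f.type not in ("CDS", "tRNA", "rRNA", "D-loop", "rep_origin", "misc_feature"):
            continue
        qual = f.qualifiers
        raw = (qual.get("gene") or qual.get("product") or [f.type])[0]
        if f.type == "D-loop":
            raw = "D-loop"
        if f.type == "rep_origin":
            raw = "OL"
        anticodon = None
        if "anticodon" in qual:
            m = re.search(r"seq:([acgtu]+)", qual["anticodon"][0], re.I)
            if m:
                anticodon = m.group(1).upper()
        name = canonical_name(raw, anticodon=anticodon)
        kind = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                "D-loop": "CR", "rep_origin": "OL"}.get(f.type, infer_kind(name))
        # Biopython locations are 0-based half-open; compound locations that
        # span the origin are collapsed to a wrap-around feature.
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        if len(parts) > 1 and int(parts[-1].end) == len(seq) and int(parts[0].start) == 0:
            start = int(parts[1].start) + 1
            end = int(parts[0].end)
        strand = "L" if f.location.strand == -1 else "H"
        feats.append(GeneFeature(name, kind, start, end, strand,
                                 anticodon=anticodon))
    if not feats:
        msg = f"{record.id}: GenBank record has no gene features"
        warnings.warn(msg)
        notes.append(msg)
    return MitoGenome(id=record.id, sequence=seq, features=feats, warnings=notes)


_COLUMN_ALIASES = {
    "gene": "gene", "feature": "gene", "features": "gene", "name": "gene",
    "start": "start", "stop": "stop", "end": "stop",
    "length": "length", "length/bp": "length", "length_bp": "length",
    "intergenic": "intergenic", "intergenicnucleotide": "intergenic",
    "igs": "intergenic",
    "start_codon": "start_codon", "startcodon": "start_codon",
    "stop_codon": "stop_codon", "stopcodon": "stop_codon",
    "anticodon": "anticodon", "anti-codon": "anticodon",
    "strand": "strand", "kind": "kind",
}


def read_feature_table(
    table: str | Path,
    fasta: str | Path | None = None,
    genome_id: str | None = None,
) -> MitoGenome:
    """Read a mitogenome from a TSV feature table plus optional FASTA.

    The table needs gene/start/stop/strand columns; a stated length column,
    when present, is cross-checked against the coordinates and any mismatch
    recorded in ``genome.warnings``.  Without a FASTA, sequence-dependent
    statistics are simply unavailable downstream.
    """
    df = pd.read_csv(table, sep="\t", dtype=str).fillna("")
    df.columns = [
        _COLUMN_ALIASES.get(c.strip().lower().replace(" ", ""), c.strip().lower())
        for c in df.columns
    ]
    required = {"gene", "start", "stop"}
    if not required.issubset(df.columns):
        raise ValueError(f"feature table must provide columns {sorted(required)}")

    seq = ""
    if fasta is not None:
        rec = next(SeqIO.parse(str(fasta), "fasta"))
        seq = str(rec.seq).upper()
        genome_id = genome_id or rec.id

    feats: list[GeneFeature] = []
    notes: list[str] = []
    seen: dict[str, tuple[int, int]] = {}
    strand_map = {"+": "H", "-": "L", "−": "L", "H": "H", "L": "L", "": "H"}
    for _, row in df.iterrows():
        name = canonical_name(str(row["gene"]),
                              anticodon=str(row.get("anticodon", "")) or None)
        start = int(str(row["start"]).replace(",", ""))
        stop = int(str(row["stop"]).replace(",", ""))
        kind = str(row.get("kind", "")) or infer_kind(name)
        strand = strand_map.get(str(row.get("strand", "H")).strip(), "H")
        if name in seen:
            if (start, stop) == seen[name]:
                raise ValueError(f"duplicate feature {name!r} with identical span")
            raise ValueError(f"overlapping duplicate gene name {name!r}")
        seen[name] = (start, stop)
        feats.append(GeneFeature(
            name, kind, start, stop, strand,
            start_codon=str(row.get("start_codon", "")) or None,
            stop_codon=str(row.get("stop_codon", "")) or None,
            anticodon=str(row.get("anticodon", "")) or None,
        ))
    genome = MitoGenome(id=genome_id or Path(str(table)).stem,
                        sequence=seq, features=feats)

    # terminal wrap is legal for the last feature only
    last_start = max(f.start for f in feats)
    for f in feats:
        if f.wraps and f.start != last_start:
            raise ValueError(
                f"{f.name}: stop < start without circular wrap "
                "(only the terminal feature may wrap the origin)")

    if "length" in df.columns:
        for f, (_, row) in zip(genome.features, df.sort_values(
                "start", key=lambda s: s.str.replace(",", "").astype(int)).iterrows()):
            stated = str(row.get("length", "")).replace(",", "")
            if stated:
                derived = f.length(genome.length)
                if int(stated) != derived:
                    notes.append(
                        f"{f.name}: stated length {stated} != coordinate "
                        f"length {derived}")
    genome.warnings.extend(notes)
    return genome


def load_reference_table(name: str = "calotomus_carolinus_table.tsv") -> MitoGenome:
    """Load the packaged parrotfish reference feature table (no sequence)."""
    with resources.as_file(resources.files("mitocomp.data") / name) as p:
        g = read_feature_table(p, genome_id="Calotomus_carolinus")
    return g


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: MitoGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")


def write_feature_table(genome: MitoGenome, path: str | Path) -> None:
    rows = []
    for f in genome.features:
        rows.append({
            "gene": f.name, "kind": f.kind, "start": f.start, "stop": f.end,
            "length": f.length(genome.length), "strand": f.strand,
            "start_codon": f.start_codon or "", "stop_codon": f.stop_codon or "",
            "anticodon": f.anticodon or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_reports(results: dict, outdir: str | Path) -> list[Path]:
    """Write one TSV per tabular result plus a JSON summary.

    ``results`` maps a report name to a DataFrame (written as ``<name>.tsv``
    with deterministic row order) or to a JSON-serialisable object (collected
    into ``summary.json``).  Reruns on identical inputs produce byte-identical
    files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary: dict = {}
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, lineterminator="\n")
            written.append(p)
        else:
            summary[name] = obj
    p = outdir / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(p)
    return written
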