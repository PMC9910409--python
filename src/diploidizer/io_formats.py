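"""Readers and writers for the external formats, plus the internal coordinate convention.

Everything in memory is 0-based, half-open (``[start, end)``).  GFF3 and
RepeatMasker ``.out`` files, which are 1-based inclusive, are converted at the
boundary in both directions, so a GFF3 -> internal -> GFF3 round trip is the
identity.

Genome units
------------
A :class:`GenomeUnit` is a diploid genome, a polyploid subgenome, or an
outgroup genome taking part in the orthogroup census.  Subgenomes live inside
a polyploid assembly and are told apart purely by chromosome-name prefixes
(e.g. ``BhD*`` vs ``BhS*``), mirroring the conventional D/S chromosome naming
of allopolyploid assemblies.  Sequences matching no unit (unplaced scaffolds)
are dropped from every analysis, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("diploidizer")

VALID_ROLES = {"diploid", "subgenome", "outgroup"}

NORMALIZED_TE_COLUMNS = [
    "copy_id", "family_id", "class_code", "chromosome",
    "start", "end", "strand", "n_fragments", "length_bp",
]


def setup_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Timestamped logging to stderr, optionally duplicated to a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    log.setLevel(level.upper())
    for h in handlers:
        h.setFormatter(fmt)
        log.addHandler(h)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeUnit:
    """A genome or subgenome participating in the census."""

    unit_id: str
    role: str
    parent_genome: str
    chromosome_patterns: tuple[str, ...]

    def __post_init__(self):
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r} for unit {self.unit_id}")
        if not self.chromosome_patterns:
            raise ValueError(f"unit {self.unit_id} declares no chromosome patterns")

    def matches(self, chromosome: str) -> bool:
        return any(chromosome.startswith(p.rstrip("*")) for p in self.chromosome_patterns)


class UnitMap:
    """Assigns chromosomes to genome units by name prefix.

    Every chromosome must match at most one unit; ambiguity is a configuration
    error and raises immediately on lookup.
    """

    def __init__(self, units: Sequence[GenomeUnit]):
        ids = [u.unit_id for u in units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit_ids in unit list")
        self.units = list(units)
        self.by_id = {u.unit_id: u for u in units}
        self._cache: dict[str, str | None] = {}

    def unit_for(self, chromosome: str) -> str | None:
        if chromosome in self._cache:
            return self._cache[chromosome]
        hits = [u.unit_id for u in self.units if u.matches(chromosome)]
        if len(hits) > 1:
            raise ValueError(
                f"chromosome {chromosome!r} matches multiple units: {hits}")
        out = hits[0] if hits else None
        self._cache[chromosome] = out
        return out

    def units_of_parent(self, parent_genome: str) -> list[GenomeUnit]:
        return [u for u in self.units if u.parent_genome == parent_genome]

    @property
    def parent_genomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for u in self.units:
            seen.setdefault(u.parent_genome)
        return list(seen)


@dataclass
class GeneModel:
    """One gene: coordinates internal (0-based half-open), plus optional sequences."""

    gene_id: str
    unit_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    rank: int = -1
    primary_transcript_length: int = 0
    cds_sequence: str | None = None
    peptide_sequence: str | None = None
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


class GeneIndex:
    """Genes of one or more units, indexed by id and by chromosome rank order.

    ``rank`` is the 0-based position of the gene along its chromosome ordered
    by start coordinate; the synteny walk moves along ranks.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        self.by_id: dict[str, GeneModel] = {}
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            if g.gene_id in self.by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.by_id[g.gene_id] = g
            self.by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom, glist in self.by_chrom.items():
            glist.sort(key=lambda g: (g.start, g.gene_id))
            for i, g in enumerate(glist):
                g.rank = i

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    def __len__(self) -> int:
        return len(self.by_id)

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self.by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in gene set") from None

    def neighbor(self, gene: GeneModel, offset: int) -> GeneModel | None:
        """Gene ``offset`` ranks away on the same chromosome, or None off the end."""
        glist = self.by_chrom[gene.chromosome]
        i = gene.rank + offset
        if 0 <= i < len(glist):
            return glist[i]
        return None

    def genes_of_unit(self, unit_id: str) -> list[GeneModel]:
        return [g for g in self.by_id.values() if g.unit_id == unit_id]


@dataclass
class Orthogroup:
    """One orthogroup: member gene ids per genome unit (empty list = absent)."""

    og_id: str
    members: dict[str, list[str]]

    def absent_units(self, unit_ids: Iterable[str]) -> set[str]:
        return {u for u in unit_ids if not self.members.get(u)}


@dataclass
class TECopy:
    """A defragmented transposable-element copy (possibly joined fragments)."""

    copy_id: str
    family_id: str
    class_code: str
    unit_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    n_fragments: int = 1
    length_bp: int = 0

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"TE copy {self.copy_id}: bad coordinates")
        if self.n_fragments < 1:
            raise ValueError(f"TE copy {self.copy_id}: n_fragments must be >= 1")
        if self.length_bp == 0:
            self.length_bp = self.end - self.start
        if self.length_bp > self.end - self.start:
            raise ValueError(
                f"TE copy {self.copy_id}: fragment length exceeds envelope")


@dataclass
class LTRPair:
    """The 5' and 3' long terminal repeats of one intact LTR retrotransposon."""

    element_id: str
    unit_id: str
    ltr5_sequence: str
    ltr3_sequence: str
    family_id: str = ""

    def __post_init__(self):
        for name, seq in (("5'", self.ltr5_sequence), ("3'", self.ltr3_sequence)):
            if not seq:
                raise ValueError(f"element {self.element_id}: empty {name} LTR")
            if set(seq) - set("ACGTN"):
                raise ValueError(
                    f"element {self.element_id}: {name} LTR has non-ACGTN characters")


class ExpressionMatrix:
    """Raw per-tissue read counts and (optionally) derived TPM values."""

    def __init__(self, counts: pd.DataFrame, tpm: pd.DataFrame | None = None):
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts
        self.tpm = tpm

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, unit_map: UnitMap,
              dropped: list[str] | None = None) -> list[GeneModel]:
    """Read gene models from GFF3, converting to internal coordinates.

    Genes on chromosomes matching no unit are dropped with a warning (their
    ids are appended to ``dropped`` when a list is supplied, so downstream
    readers can tell "unplaced" from "unknown").
    """
    path = Path(path)
    if not any(line.strip() and not line.startswith("#")
               for line in open(path)):
        return []   # vacuous input
    try:
        db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                                merge_strategy="error")
    except Exception as exc:  # gffutils raises several parse-error types
        raise ValueError(f"failed to parse GFF3 {path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene"):
        gid = feat.id
        if gid in seen:
            raise ValueError(f"duplicate gene_id {gid} in {path}")
        seen.add(gid)
        unit = unit_map.unit_for(feat.seqid)
        if unit is None:
            log.warning("gene %s on chromosome %s matches no unit; dropped",
                        gid, feat.seqid)
            if dropped is not None:
                dropped.append(gid)
            continue
        exons = []
        tx_len = 0
        for mrna in db.children(feat, featuretype="mRNA", order_by="start"):
            for ex in db.children(mrna, featuretype="exon", order_by="start"):
                exons.append((ex.start - 1, ex.end))
                tx_len += ex.end - ex.start + 1
            break  # primary transcript only
        if not exons:
            exons = [(feat.start - 1, feat.end)]
            tx_len = feat.end - feat.start + 1
        genes.append(GeneModel(
            gene_id=gid, unit_id=unit, chromosome=feat.seqid,
            start=feat.start - 1, end=feat.end, strand=feat.strand,
            primary_transcript_length=tx_len, exons=exons))
    # ranks
    GeneIndex(genes)
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path,
               source: str = "diploidizer") -> None:
    """Write gene models as GFF3 (gene + mRNA + exon features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(f"{g.chromosome}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{g.chromosome}\t{source}\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n")
            exons = g.exons or [(g.start, g.end)]
            for k, (s, e) in enumerate(exons, 1):
                fh.write(f"{g.chromosome}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={mrna}.exon{k};Parent={mrna}\n")


def attach_sequences(genes: Iterable[GeneModel],
                     cds_fasta: str | Path | None = None,
                     pep_fasta: str | Path | None = None) -> None:
    """Attach CDS / peptide sequences from FASTA files keyed by gene id."""
    cds = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(cds_fasta), "fasta")} \
        if cds_fasta else {}
    pep = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(pep_fasta), "fasta")} \
        if pep_fasta else {}
    for g in genes:
        if g.gene_id in cds:
            g.cds_sequence = cds[g.gene_id]
        if g.gene_id in pep:
            g.peptide_sequence = pep[g.gene_id]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path, unit_map: UnitMap, gene_index: GeneIndex,
                     unplaced_ids: frozenset[str] | set[str] = frozenset(),
                     ) -> list[Orthogroup]:
    """Read an orthogroup table (og_id column + one comma-separated column per
    parent genome) and resolve polyploid genes to subgenome units by chromosome
    pattern.

    Gene ids in ``unplaced_ids`` (e.g. genes on unplaced scaffolds dropped by
    :func:`read_gff3`) are excluded with a warning; any other id absent from
    the gene set is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    og_col = df.columns[0]
    parents = [c for c in df.columns[1:]]
    unit_ids = [u.unit_id for u in unit_map.units]
    offenders: list[str] = []
    out: list[Orthogroup] = []
    for _, row in df.iterrows():
        members: dict[str, list[str]] = {u: [] for u in unit_ids}
        for parent in parents:
            cell = row[parent].strip()
            if not cell:
                continue
            for gid in (x.strip() for x in cell.split(",")):
                if not gid:
                    continue
                if gid in unplaced_ids:
                    log.warning("orthogroup %s: gene %s is on an unplaced "
                                "scaffold; excluded", row[og_col], gid)
                    continue
                if gid not in gene_index:
                    offenders.append(gid)
                    continue
                gene = gene_index.get(gid)
                unit = unit_map.unit_for(gene.chromosome)
                if unit is None:
                    log.warning("orthogroup %s: gene %s matches no unit; excluded",
                                row[og_col], gid)
                    continue
                members[unit].append(gid)
        out.append(Orthogroup(og_id=row[og_col], members=members))
    if offenders:
        raise ValueError(
            f"orthogroup table {path} references genes absent from the gene set: "
            f"{sorted(set(offenders))[:20]}"
            + (" ..." if len(set(offenders)) > 20 else ""))
    return out


def write_orthogroups(orthogroups: Sequence[Orthogroup], unit_map: UnitMap,
                      path: str | Path) -> None:
    """Write orthogroups with one column per parent genome (subgenome columns merged)."""
    parents = unit_map.parent_genomes
    rows = []
    for og in orthogroups:
        row = {"Orthogroup": og.og_id}
        for parent in parents:
            ids: list[str] = []
            for u in unit_map.units_of_parent(parent):
                ids.extend(og.members.get(u.unit_id, []))
            row[parent] = ", ".join(ids)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# TE tables
# ---------------------------------------------------------------------------

# RepeatMasker class/family vocabulary -> unified 3-letter codes.  Anything
# unrecognized maps to "Unknown" rather than erroring: the vocabulary is
# irregular across library versions.
_CLASS_MAP = {
    "LTR/GYPSY": "RLG", "LTR/COPIA": "RLC", "LTR": "RLX", "LTR/UNKNOWN": "RLX",
    "LTR/CAULIMOVIRUS": "RLX", "LINE": "RIX", "LINE/L1": "RIX", "LINE/RTE": "RIX",
    "SINE": "RSX", "DNA": "DTX", "DNA/CMC-ENSPM": "DTC", "DNA/HAT": "DTA",
    "DNA/MULE-MUDR": "DTM", "DNA/PIF-HARBINGER": "DTH", "DNA/TCMAR": "DTT",
    "MITE": "DXX", "RC/HELITRON": "DHH", "SIMPLE_REPEAT": "Unknown",
    "LOW_COMPLEXITY": "Unknown",
}
_KNOWN_CODES = {"RLG", "RLC", "RLX", "RIX", "RSX",
                "DTX", "DTC", "DTA", "DTM", "DTH", "DTT", "DXX", "DHH"}


def normalize_class_code(raw: str) -> str:
    raw = raw.strip()
    if raw in _KNOWN_CODES:
        return raw
    return _CLASS_MAP.get(raw.upper(), "Unknown")


def read_te_table(path: str | Path, dialect: str, unit_map: UnitMap) -> list[TECopy]:
    """Read TE copies from a normalized TSV or a RepeatMasker ``.out`` file.

    ``.out`` rows sharing an ID (column 15, as left by a defragmentation step)
    are merged into a single copy whose envelope spans all fragments and whose
    ``length_bp`` is the summed fragment spans.
    """
    if dialect == "normalized_tsv":
        return _read_te_tsv(path, unit_map)
    if dialect == "repeatmasker_out":
        return _read_rm_out(path, unit_map)
    raise ValueError(f"unknown TE table dialect {dialect!r}")


def _keep_te(chrom: str, unit_map: UnitMap, copy_id: str) -> str | None:
    unit = unit_map.unit_for(chrom)
    if unit is None:
        log.warning("TE copy %s on chromosome %s matches no unit; dropped",
                    copy_id, chrom)
    return unit


def _read_te_tsv(path: str | Path, unit_map: UnitMap) -> list[TECopy]:
    df = pd.read_csv(path, sep="\t", dtype={"copy_id": str, "family_id": str})
    missing = set(NORMALIZED_TE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"TE TSV {path} lacks columns {sorted(missing)}")
    if (df["start"] < 0).any():
        raise ValueError(f"TE TSV {path} has negative coordinates")
    out = []
    for row in df.itertuples(index=False):
        unit = _keep_te(row.chromosome, unit_map, row.copy_id)
        if unit is None:
            continue
        out.append(TECopy(
            copy_id=str(row.copy_id), family_id=str(row.family_id),
            class_code=normalize_class_code(str(row.class_code)), unit_id=unit,
            chromosome=row.chromosome, start=int(row.start), end=int(row.end),
            strand=row.strand, n_fragments=int(row.n_fragments),
            length_bp=int(row.length_bp)))
    return out


def _read_rm_out(path: str | Path, unit_map: UnitMap) -> list[TECopy]:
    frags: dict[str, list[dict]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or not parts[0].isdigit():
                continue  # the 3-line header, or blank
            if len(parts) < 15:
                raise ValueError(f"malformed RepeatMasker row in {path}: {line!r}")
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            if begin < 1 or end < begin:
                raise ValueError(f"negative/inverted coordinates in {path}: {line!r}")
            strand = "+" if parts[8] == "+" else "-"
            family, klass, copy_id = parts[9], parts[10], parts[14]
            rec = dict(chromosome=chrom, start=begin - 1, end=end, strand=strand,
                       family_id=family, class_code=normalize_class_code(klass))
            if copy_id not in frags:
                order.append(copy_id)
            frags.setdefault(copy_id, []).append(rec)
    out = []
    for copy_id in order:
        rows = frags[copy_id]
        chrom = rows[0]["chromosome"]
        unit = _keep_te(chrom, unit_map, copy_id)
        if unit is None:
            continue
        start = min(r["start"] for r in rows)
        end = max(r["end"] for r in rows)
        out.append(TECopy(
            copy_id=copy_id, family_id=rows[0]["family_id"],
            class_code=rows[0]["class_code"], unit_id=unit, chromosome=chrom,
            start=start, end=end, strand=rows[0]["strand"],
            n_fragments=len(rows),
            length_bp=sum(r["end"] - r["start"] for r in rows)))
    return out


def write_te_table(copies: Sequence[TECopy], path: str | Path) -> None:
    rows = [{c: getattr(te, c) for c in NORMALIZED_TE_COLUMNS} for te in copies]
    pd.DataFrame(rows, columns=NORMALIZED_TE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LTR pairs
# ---------------------------------------------------------------------------

def read_ltr_pairs(path: str | Path, unit_map: UnitMap | None = None,
                   unit_of: Mapping[str, str] | None = None) -> list[LTRPair]:
    """Read paired-LTR FASTA with headers ``element|5p`` / ``element|3p``.

    Sequences are uppercased on read.  ``unit_of`` optionally maps element ids
    to genome units (ids formatted ``unit:element`` are parsed automatically).
    """
    five: dict[str, str] = {}
    three: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"LTR FASTA header {rec.id!r} lacks |5p / |3p suffix")
        element, tag = rec.id.rsplit("|", 1)
        seq = str(rec.seq).upper()
        if tag == "5p":
            five[element] = seq
        elif tag == "3p":
            three[element] = seq
        else:
            raise ValueError(f"LTR FASTA header {rec.id!r}: unknown tag {tag!r}")
        if element not in order:
            order.append(element)
    orphans = sorted(set(five) ^ set(three))
    if orphans:
        raise ValueError(f"LTR elements missing one LTR: {orphans}")
    out = []
    for element in order:
        unit, family = "", ""
        if ":" in element:
            unit = element.split(":", 1)[0]
        if unit_of and element in unit_of:
            unit = unit_of[element]
        if "#" in element:
            family = element.split("#", 1)[1]
        out.append(LTRPair(element_id=element, unit_id=unit,
                           ltr5_sequence=five[element],
                           ltr3_sequence=three[element], family_id=family))
    return out


def write_ltr_pairs(pairs: Sequence[LTRPair], path: str | Path) -> None:
    seqs: dict[str, str] = {}
    for p in pairs:
        seqs[f"{p.element_id}|5p"] = p.ltr5_sequence
        seqs[f"{p.element_id}|3p"] = p.ltr3_sequence
    write_fasta(seqs, path)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> ExpressionMatrix:
    """Read a gene x tissue integer count table (TSV, gene ids in column 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene rows in {path}: {dups[:10]}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().values)[0]
        raise ValueError(f"missing cell in {path} at gene {df.index[r]!r} "
                         f"tissue {df.columns[c]!r}")
    try:
        num = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if not np.equal(np.mod(num.values, 1), 0).all():
        raise ValueError(f"non-integer cell in {path}")
    if (num.values < 0).any():
        raise ValueError(f"negative count in {path}")
    return ExpressionMatrix(counts=num.astype("int64"))


def write_counts(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.counts if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def units_from_config(cfg: dict) -> UnitMap:
    units = [GenomeUnit(unit_id=u["unit_id"], role=u["role"],
                        parent_genome=u["parent_genome"],
                        chromosome_patterns=tuple(u["chromosome_patterns"]))
             for u in cfg.get("units", [])]
    return UnitMap(units)
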