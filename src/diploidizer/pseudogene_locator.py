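"""The synteny walk: find the polyploid interval where a missing gene should be.

Starting from the diploid progenitor gene corresponding to a missing
polyploid gene, walk outward along the diploid chromosome in both
directions.  A neighbor is *informative* when it has exactly one ortholog in
the target subgenome; genes with zero or several orthologs are skipped.  The
walk fails if more than ``max_checked_per_side`` genes must be examined on a
side, or if the chromosome end arrives before ``neighbors_per_side``
informative neighbors were found.

The informative neighbors' orthologs must then agree on a locus: some window
of ``consensus_window_bp`` on a single polyploid chromosome has to contain at
least ``min_in_window_per_side`` ortholog positions from *each* side
simultaneously (a joint window — the anchors from both sides must bound one
region).  The anchors are the in-window orthologs of the informative
neighbors closest (by rank) to the diploid gene on each side; the candidate
region runs from the leftmost anchor start to the rightmost anchor end and is
discarded when longer than ``max_region_bp``.

Every discard carries its reason, so the attrition funnel of a run can be
reported stage by stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import GeneIndex, GeneModel, Orthogroup

# walk-failure / discard statuses
LOCATED = "located"
DISCARD_WALK_LIMIT = "discard_walk_limit"
DISCARD_CHROM_END = "discard_chromosome_end"
DISCARD_WINDOW = "discard_window"
DISCARD_REGION_SIZE = "discard_region_size"


@dataclass(frozen=True)
class WalkParams:
    neighbors_per_side: int = 5
    max_checked_per_side: int = 25
    consensus_window_bp: int = 200_000
    min_in_window_per_side: int = 4
    max_region_bp: int = 20_000

    def __post_init__(self):
        vals = (self.neighbors_per_side, self.max_checked_per_side,
                self.consensus_window_bp, self.min_in_window_per_side,
                self.max_region_bp)
        if any(v <= 0 for v in vals):
            raise ValueError("all walk parameters must be positive")
        if self.min_in_window_per_side > self.neighbors_per_side:
            raise ValueError("min_in_window_per_side > neighbors_per_side")


@dataclass
class CandidateRegion:
    og_id: str
    missing_unit: str
    diploid_gene_id: str
    status: str
    target_chromosome: str = ""
    start: int = -1
    end: int = -1
    upstream_anchor_gene: str = ""
    downstream_anchor_gene: str = ""
    informative_neighbors: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start if self.status == LOCATED else -1


class WalkFailure(Exception):
    def __init__(self, status: str):
        self.status = status
        super().__init__(status)


def informative_neighbors(diploid_gene: GeneModel, direction: int,
                          ortholog_map: Mapping[str, Sequence[str]],
                          diploid_index: GeneIndex,
                          params: WalkParams) -> tuple[list[tuple[str, str]], int]:
    """Walk outward from ``diploid_gene`` (direction -1 upstream / +1
    downstream by rank) and return the first ``neighbors_per_side``
    single-ortholog neighbors as ``(diploid_gene_id, ortholog_id)`` pairs,
    plus the number of genes examined.

    Raises :class:`WalkFailure` with the discard reason when the per-side
    check limit is exceeded or the chromosome end is reached first.  The
    diploid gene itself is not counted toward the limit.
    """
    if diploid_gene.gene_id not in diploid_index:
        raise KeyError(f"gene {diploid_gene.gene_id} not in gene set")
    found: list[tuple[str, str]] = []
    checked = 0
    offset = 0
    while len(found) < params.neighbors_per_side:
        offset += 1
        if checked + 1 > params.max_checked_per_side:
            raise WalkFailure(DISCARD_WALK_LIMIT)
        neighbor = diploid_index.neighbor(diploid_gene, direction * offset)
        if neighbor is None:
            raise WalkFailure(DISCARD_CHROM_END)
        checked += 1
        orths = ortholog_map.get(neighbor.gene_id, ())
        if len(orths) == 1:
            found.append((neighbor.gene_id, orths[0]))
    return found, checked


def locate(og: Orthogroup, missing_unit: str, diploid_gene: GeneModel,
           ortholog_map: Mapping[str, Sequence[str]],
           diploid_index: GeneIndex, polyploid_index: GeneIndex,
           params: WalkParams = WalkParams()) -> CandidateRegion:
    """Run the full walk + consensus-window + anchor-extraction funnel for one
    single-missing orthogroup."""
    region = CandidateRegion(og_id=og.og_id, missing_unit=missing_unit,
                             diploid_gene_id=diploid_gene.gene_id, status="")
    sides: dict[str, list[tuple[str, str]]] = {}
    try:
        for label, direction in (("upstream", -1), ("downstream", +1)):
            found, _ = informative_neighbors(diploid_gene, direction,
                                             ortholog_map, diploid_index, params)
            sides[label] = found
    except WalkFailure as wf:
        region.status = wf.status
        region.informative_neighbors = sides
        return region
    region.informative_neighbors = sides

    # entries: (side, rank_distance, ortholog GeneModel); rank distance is the
    # 1-based position in the walk order, i.e. closest informative first
    entries: list[tuple[str, int, GeneModel]] = []
    for side in ("upstream", "downstream"):
        for dist, (_, orth_id) in enumerate(sides[side], start=1):
            entries.append((side, dist, polyploid_index.get(orth_id)))

    best = _best_window(entries, params)
    if best is None:
        region.status = DISCARD_WINDOW
        return region
    chrom, up_anchor, down_anchor = best
    start = min(up_anchor.start, down_anchor.start)
    end = max(up_anchor.end, down_anchor.end)
    region.target_chromosome = chrom
    region.start, region.end = start, end
    region.upstream_anchor_gene = up_anchor.gene_id
    region.downstream_anchor_gene = down_anchor.gene_id
    if end - start > params.max_region_bp:
        region.status = DISCARD_REGION_SIZE
        return region
    region.status = LOCATED
    return region


def _best_window(entries: list[tuple[str, int, GeneModel]], params: WalkParams,
                 ) -> tuple[str, GeneModel, GeneModel] | None:
    """Scan candidate ``consensus_window_bp`` windows on each chromosome for
    one holding >= ``min_in_window_per_side`` ortholog positions from each
    side; among qualifying windows return the one minimizing the final anchor
    region span (ties: leftmost).  Positions are compared by gene start."""
    by_chrom: dict[str, list[tuple[str, int, GeneModel]]] = {}
    for e in entries:
        by_chrom.setdefault(e[2].chromosome, []).append(e)

    best: tuple[int, int, str, GeneModel, GeneModel] | None = None
    for chrom in sorted(by_chrom):
        ents = sorted(by_chrom[chrom], key=lambda e: (e[2].start, e[2].gene_id))
        n = len(ents)
        j = 0
        for i in range(n):   # window anchored at each ortholog start
            lo = ents[i][2].start
            while j < n and ents[j][2].start <= lo + params.consensus_window_bp:
                j += 1
            window = ents[i:j]
            n_up = sum(1 for s, _, _ in window if s == "upstream")
            n_down = sum(1 for s, _, _ in window if s == "downstream")
            if n_up < params.min_in_window_per_side \
                    or n_down < params.min_in_window_per_side:
                continue
            up = min((e for e in window if e[0] == "upstream"),
                     key=lambda e: (e[1], e[2].start))[2]
            down = min((e for e in window if e[0] == "downstream"),
                       key=lambda e: (e[1], e[2].start))[2]
            span = max(up.end, down.end) - min(up.start, down.start)
            key = (span, min(up.start, down.start), chrom, up, down)
            if best is None or key[:2] < best[:2]:
                best = key
    if best is None:
        return None
    _, _, chrom, up, down = best
    return chrom, up, down


def extract_region(candidate: CandidateRegion, polyploid_fasta: Mapping[str, str],
                   ) -> str:
    """Forward-strand genomic substring of a located candidate region."""
    if candidate.status != LOCATED:
        raise ValueError(f"candidate {candidate.og_id} is not located "
                         f"(status {candidate.status})")
    chrom_seq = polyploid_fasta[candidate.target_chromosome]
    if candidate.end > len(chrom_seq) or candidate.start < 0:
        raise ValueError(
            f"region {candidate.start}-{candidate.end} exceeds chromosome "
            f"{candidate.target_chromosome} length {len(chrom_seq)}")
    return chrom_seq[candidate.start:candidate.end]


def build_ortholog_map(orthogroups: Sequence[Orthogroup], diploid_unit: str,
                       target_unit: str) -> dict[str, list[str]]:
    """diploid gene id -> list of orthologs in the target subgenome unit."""
    omap: dict[str, list[str]] = {}
    for og in orthogroups:
        targets = og.members.get(target_unit, [])
        for gid in og.members.get(diploid_unit, []):
            omap.setdefault(gid, []).extend(targets)
    return omap


def locate_all(orthogroups: Sequence[Orthogroup],
               patterns_by_og: Mapping[str, frozenset[str]],
               subgenome_to_progenitor: Mapping[str, str],
               gene_index: GeneIndex,
               params: WalkParams = WalkParams()) -> list[CandidateRegion]:
    """Locate every orthogroup that is single-missing in a polyploid subgenome.

    ``patterns_by_og`` maps og_id -> absent unit set (from the census);
    deterministic over input order: orthogroups are processed sorted by id.
    """
    omaps = {sub: build_ortholog_map(orthogroups, dip, sub)
             for sub, dip in subgenome_to_progenitor.items()}
    out: list[CandidateRegion] = []
    for og in sorted(orthogroups, key=lambda o: o.og_id):
        absent = patterns_by_og.get(og.og_id)
        if absent is None or len(absent) != 1:
            continue
        missing_unit = next(iter(absent))
        if missing_unit not in subgenome_to_progenitor:
            continue
        dip_unit = subgenome_to_progenitor[missing_unit]
        dip_members = og.members.get(dip_unit, [])
        if not dip_members:
            continue
        diploid_gene = gene_index.get(sorted(dip_members)[0])
        out.append(locate(og, missing_unit, diploid_gene, omaps[missing_unit],
                          gene_index, gene_index, params))
    return out
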