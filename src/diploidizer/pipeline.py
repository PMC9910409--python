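"""Run the whole analysis — census -> locate -> characterize -> expression ->
TE statistics — from one config file, with a machine-readable report and a
reproducibility manifest.

The config is a YAML mapping (the synthetic generator writes a valid one next
to its outputs) declaring the genome units, the subgenome -> progenitor
correspondence, the polyploid assembly name, tissues, and input file names.

Each stochastic stage receives a child seed derived by stable hashing of
``(seed, stage name)``, so adding a stage never perturbs another stage's
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

from . import __version__
from .expression_bias import bias_table, counts_to_tpm, subgenome_dominance
from .io_formats import (GeneIndex, UnitMap, attach_sequences, load_config,
                         read_counts, read_fasta, read_gff3, read_ltr_pairs,
                         read_orthogroups, read_te_table, units_from_config)
from .orthogroup_census import census, census_table
from .pseudogene_characterizer import (PseudogeneReport, characterize,
                                       characterize_own_locus, control_trials,
                                       nonexpression_enrichment)
from .pseudogene_locator import (LOCATED, WalkParams, extract_region,
                                 locate_all)
from .te_analysis import (classify_specificity, composition_summary,
                          date_ltr_pairs, family_age_profile, gene_te_overlap,
                          gypsy_copia_ratios)

log = logging.getLogger("diploidizer")

ALL_STAGES = ("census", "locate", "characterize", "expression", "te")


def child_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def validate_config(cfg: dict, base_dir: str | Path = ".") -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems: list[str] = []
    base = Path(base_dir)
    units = cfg.get("units")
    if not units:
        problems.append("no units declared")
    else:
        seen = set()
        for u in units:
            uid = u.get("unit_id", "<missing>")
            if uid in seen:
                problems.append(f"duplicate unit_id {uid}")
            seen.add(uid)
            if u.get("role") not in {"diploid", "subgenome", "outgroup"}:
                problems.append(f"unit {uid}: bad role {u.get('role')!r}")
            if not u.get("chromosome_patterns"):
                problems.append(f"unit {uid} has no chromosome patterns")
    s2p = cfg.get("subgenome_to_progenitor", {})
    unit_ids = {u.get("unit_id") for u in units or []}
    for sub, dip in s2p.items():
        if sub not in unit_ids or dip not in unit_ids:
            problems.append(f"subgenome_to_progenitor {sub}->{dip} names "
                            "undeclared units")
    files = cfg.get("files", {})
    for key, name in files.items():
        if not (base / name).exists():
            problems.append(f"input file for {key!r} not found: {name}")
    params = cfg.get("parameters", {})
    thr = params.get("specificity_threshold", 0.90)
    if not (0.0 < thr <= 1.0):
        problems.append(f"specificity_threshold {thr} outside (0, 1]")
    mc = params.get("specificity_min_copies", 5)
    if mc < 1:
        problems.append("specificity_min_copies must be >= 1")
    for k in ("neighbors_per_side", "max_checked_per_side",
              "consensus_window_bp", "min_in_window_per_side", "max_region_bp"):
        if k in params and params[k] <= 0:
            problems.append(f"walk parameter {k} must be positive")
    if "expression" in cfg.get("stages", ALL_STAGES) and files \
            and "counts" not in files:
        problems.append("expression stage enabled but no counts file declared")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class Pipeline:
    """Loads a dataset directory and runs the analysis stages."""

    def __init__(self, config_path: str | Path, seed: int = 0):
        self.base = Path(config_path).parent
        self.cfg = load_config(config_path)
        problems = validate_config(self.cfg, self.base)
        if problems:
            raise ValueError("invalid config:\n  " + "\n  ".join(problems))
        self.seed = seed
        self.unit_map: UnitMap = units_from_config(self.cfg)
        self.s2p: dict[str, str] = dict(self.cfg["subgenome_to_progenitor"])
        self.polyploid: str = self.cfg["polyploid"]
        self.tissues: list[str] = list(self.cfg.get("tissues", []))
        files = self.cfg["files"]
        self._f = {k: self.base / v for k, v in files.items()}
        params = self.cfg.get("parameters", {})
        self.walk_params = WalkParams(**{
            k: params[k] for k in ("neighbors_per_side", "max_checked_per_side",
                                   "consensus_window_bp",
                                   "min_in_window_per_side", "max_region_bp")
            if k in params})
        self._load_inputs()

    def _load_inputs(self) -> None:
        genes = []
        self.dropped: list[str] = []
        assemblies = sorted({k.split(".")[0] for k in self._f
                             if k.endswith(".gff3")})
        for assembly in assemblies:
            a_genes = read_gff3(self._f[f"{assembly}.gff3"], self.unit_map,
                                dropped=self.dropped)
            attach_sequences(a_genes,
                             cds_fasta=self._f.get(f"{assembly}.cds"),
                             pep_fasta=self._f.get(f"{assembly}.pep"))
            genes.extend(a_genes)
        self.genes = GeneIndex(genes)
        self.orthogroups = read_orthogroups(
            self._f["orthogroups"], self.unit_map, self.genes,
            unplaced_ids=frozenset(self.dropped))
        self.polyploid_fasta = read_fasta(self._f[f"{self.polyploid}.genome"])
        self.te_copies = read_te_table(self._f["te"], "normalized_tsv",
                                       self.unit_map) if "te" in self._f else []
        self.ltr_pairs = read_ltr_pairs(self._f["ltr"]) if "ltr" in self._f else []
        self.counts = read_counts(self._f["counts"]) if "counts" in self._f else None
        self.pairs = pd.read_csv(self._f["pairs"], sep="\t") \
            if "pairs" in self._f else None

    # ---- stages ----------------------------------------------------------

    def run_census(self) -> dict[str, Any]:
        unit_ids = [u.unit_id for u in self.unit_map.units]
        self.patterns, self.category_counts = census(self.orthogroups, unit_ids)
        return {"n_orthogroups": len(self.patterns),
                "categories": dict(self.category_counts)}

    def run_locate(self) -> dict[str, Any]:
        by_og = {p.og_id: p.absent_units for p in self.patterns}
        self.candidates = locate_all(self.orthogroups, by_og, self.s2p,
                                     self.genes, self.walk_params)
        funnel = Counter(c.status for c in self.candidates)
        return {"n_single_missing": len(self.candidates),
                "funnel": dict(funnel)}

    def _tpm_with_remnants(self) -> pd.DataFrame | None:
        """TPM over annotated polyploid genes plus any remnant rows in the
        counts table; remnant lengths are their candidate-region spans."""
        if self.counts is None:
            return None
        lengths = {g.gene_id: g.primary_transcript_length
                   for g in self.genes.by_id.values()}
        for c in getattr(self, "candidates", []):
            if c.status == LOCATED:
                rid = self._remnant_counts_id(c)
                if rid is not None:
                    lengths.setdefault(rid, c.end - c.start)
        keep = [g for g in self.counts.counts.index if g in lengths]
        from .io_formats import ExpressionMatrix
        sub = ExpressionMatrix(self.counts.counts.loc[keep])
        return counts_to_tpm(sub, {g: lengths[g] for g in keep}).tpm

    def _remnant_counts_id(self, candidate) -> str | None:
        """Counts rows for unannotated remnants are keyed, by convention, by
        the gene id the locus would have carried: the diploid ortholog's id
        with the unit prefix replaced by the missing subgenome's."""
        if self.counts is None:
            return None
        dip_unit = self.s2p[candidate.missing_unit]
        dip = candidate.diploid_gene_id
        if dip.startswith(dip_unit):
            rid = candidate.missing_unit + dip[len(dip_unit):]
            if rid in self.counts.counts.index:
                return rid
        return None

    def run_characterize(self, n_trials: int = 1000, per_trial_d: int = 224,
                         per_trial_s: int = 240) -> dict[str, Any]:
        tpm = self._tpm_with_remnants()
        located = [c for c in self.candidates if c.status == LOCATED]
        self.reports: list[PseudogeneReport] = []
        for c in located:
            dip = self.genes.get(c.diploid_gene_id)
            region = extract_region(c, self.polyploid_fasta)
            rid = self._remnant_counts_id(c)
            row = tpm.loc[rid].to_dict() if (tpm is not None and rid) else None
            self.reports.append(characterize(
                c, region, dip.cds_sequence, dip.peptide_sequence,
                te_copies=[t for t in self.te_copies
                           if t.chromosome == c.target_chromosome],
                tpm_row=row, gene_id=rid or ""))
        aligned = [r for r in self.reports if r.aligned]

        # conserved control pools: annotated polyploid genes from complete
        # orthogroups, characterized on their own locus
        complete = {p.og_id for p in self.patterns if p.category == "complete"}
        pools: dict[str, list[PseudogeneReport]] = {u: [] for u in self.s2p}
        for og in self.orthogroups:
            if og.og_id not in complete:
                continue
            for sub, dip_unit in self.s2p.items():
                for gid in og.members.get(sub, []):
                    gene = self.genes.get(gid)
                    dips = og.members.get(dip_unit, [])
                    if not dips:
                        continue
                    dip = self.genes.get(sorted(dips)[0])
                    row = tpm.loc[gid].to_dict() \
                        if tpm is not None and gid in tpm.index else None
                    pools[sub].append(characterize_own_locus(
                        gene, self.polyploid_fasta[gene.chromosome],
                        dip.cds_sequence, dip.peptide_sequence,
                        te_copies=[t for t in self.te_copies
                                   if t.chromosome == gene.chromosome],
                        tpm_row=row))
        subs = sorted(self.s2p)
        d_unit, s_unit = subs[0], subs[-1]
        per_trial_d = min(per_trial_d, len(pools[d_unit]))
        per_trial_s = min(per_trial_s, len(pools[s_unit]))
        self.control = control_trials(
            pools[d_unit], pools[s_unit], n_trials=n_trials,
            per_trial_d=per_trial_d, per_trial_s=per_trial_s,
            seed=child_seed(self.seed, "control"), tissues=self.tissues)
        self.control_pools = pools

        def cohort(reports: Iterable[PseudogeneReport]) -> dict[str, float]:
            reports = list(reports)
            omegas = [r.omega for r in reports if r.omega_valid]
            tpms = [float(np.mean(list(r.tpm_per_tissue.values())))
                    for r in reports if r.tpm_per_tissue]
            return {
                "n": len(reports),
                "mean_length_deficit": float(np.mean(
                    [r.length_deficit_bp for r in reports])) if reports else float("nan"),
                "pct_ptc": 100.0 * float(np.mean([r.has_ptc for r in reports]))
                if reports else float("nan"),
                "mean_omega": float(np.mean(omegas)) if omegas else float("nan"),
                "n_omega_valid": len(omegas),
                "median_tpm": float(np.median(tpms)) if tpms else float("nan"),
                "pct_te_contained": 100.0 * float(np.mean(
                    [r.te_contained for r in reports])) if reports else float("nan"),
            }

        summary = {
            "pseudogenes": cohort(aligned),
            "n_candidates": len(self.candidates),
            "n_located": len(located),
            "n_aligned": len(aligned),
            "control_mean": {m: float(self.control.trials[m].mean())
                             for m in self.control.trials.columns},
            "empirical_p": {
                m: self.control.empirical_p(v, m, "greater")
                for m, v in (
                    ("mean_length_deficit", cohort(aligned)["mean_length_deficit"]),
                    ("ptc_fraction", cohort(aligned)["pct_ptc"] / 100.0),
                    ("mean_omega", cohort(aligned)["mean_omega"]),
                ) if not math_isnan(v)},
        }
        if self.tissues and any(r.nonexpressed_per_tissue for r in aligned):
            enrich = {}
            for t in self.tissues:
                flags = [r.nonexpressed_per_tissue.get(t) for r in aligned
                         if r.nonexpressed_per_tissue]
                if flags:
                    enrich[t] = nonexpression_enrichment(
                        sum(flags), len(flags),
                        self.control.expected_nonexpressed_freq(t))
            summary["nonexpression_p"] = enrich
        return summary

    def run_expression(self) -> dict[str, Any]:
        if self.counts is None or self.pairs is None:
            return {"skipped": "no counts/pairs input"}
        lengths = {g.gene_id: g.primary_transcript_length
                   for g in self.genes.by_id.values()}
        keep = [g for g in self.counts.counts.index if g in lengths]
        from .io_formats import ExpressionMatrix
        sub = ExpressionMatrix(self.counts.counts.loc[keep])
        mat = counts_to_tpm(sub, {g: lengths[g] for g in keep})
        self.bias = bias_table(self.pairs, mat.tpm, self.tissues)
        subs = sorted(self.s2p)
        gene_units = {g: self.genes.get(g).unit_id for g in keep}
        self.dominance = [
            subgenome_dominance(mat, gene_units, lengths, t, subs[0], subs[-1])
            for t in self.tissues]
        return {
            "bias": self.bias.to_dict(orient="records"),
            "dominance": [dataclasses.asdict(d) for d in self.dominance]}

    def run_te(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        if self.te_copies:
            comp = composition_summary(self.te_copies)
            subs = sorted(self.s2p)
            fams, pct, per_chrom = classify_specificity(
                self.te_copies, subs[0], subs[-1])
            poly_genes = [g for g in self.genes.by_id.values()
                          if g.unit_id in self.s2p]
            stats = gene_te_overlap(poly_genes, self.te_copies)
            self.te_summary = dict(composition=comp, families=fams,
                                   pct_specific=pct, per_chrom=per_chrom,
                                   gene_te=stats)
            out.update({
                "pct_copies_in_specific_families": pct,
                "gypsy_copia": gypsy_copia_ratios(comp).to_dict(orient="records"),
                "pct_genes_overlapping_te": stats.pct_genes_overlapping_te,
                "mean_te_gene_distance_bp": stats.mean_te_gene_distance_bp})
        if self.ltr_pairs:
            dated, excluded = date_ltr_pairs(self.ltr_pairs)
            self.dated_ltrs = dated
            profile = family_age_profile(dated)
            out.update({
                "n_dated_ltrs": len(dated), "n_excluded_ltrs": len(excluded),
                "young_ltr_fraction": profile.young_fraction,
                "young_ltr_fraction_per_unit": profile.young_fraction_per_unit})
        return out

    # ---- orchestration ---------------------------------------------------

    def run_all(self, out_dir: str | Path,
                stages: Iterable[str] = ALL_STAGES,
                n_trials: int = 1000) -> dict[str, Any]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stages = list(stages)
        report: dict[str, Any] = {}
        # census and locate are prerequisites of characterize
        need = set(stages)
        if "characterize" in need:
            need.update(("census", "locate"))
        for stage in ALL_STAGES:
            if stage not in need:
                continue
            try:
                report[stage] = getattr(self, f"run_{stage}")() \
                    if stage != "characterize" \
                    else self.run_characterize(n_trials=n_trials)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            self._write_stage(stage, out)
        manifest = {
            "version": __version__,
            "seed": self.seed,
            "stage_seeds": {s: child_seed(self.seed, s) for s in ALL_STAGES},
            "config_sha256": _sha256(self.base / "config.yaml")
            if (self.base / "config.yaml").exists() else None,
            "input_sha256": {k: _sha256(p) for k, p in sorted(self._f.items())},
            "walk_params": dataclasses.asdict(self.walk_params),
            "stages": list(stages),
            "outputs": sorted(p.name for p in out.iterdir()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        return report

    def _write_stage(self, stage: str, out: Path) -> None:
        if stage == "census":
            census_table(self.patterns).to_csv(out / "census_patterns.tsv",
                                               sep="\t", index=False)
            pd.Series(dict(self.category_counts), name="count") \
                .rename_axis("category").reset_index() \
                .to_csv(out / "census_counts.tsv", sep="\t", index=False)
        elif stage == "locate":
            rows = [dataclasses.asdict(c) for c in self.candidates]
            for r in rows:
                r.pop("informative_neighbors")
            pd.DataFrame(rows).to_csv(out / "candidate_status.tsv",
                                      sep="\t", index=False)
            with open(out / "candidate_regions.bed", "w") as fh:
                for c in self.candidates:
                    if c.status == LOCATED:
                        fh.write(f"{c.target_chromosome}\t{c.start}\t{c.end}\t"
                                 f"{c.og_id}\n")
        elif stage == "characterize":
            pd.DataFrame([dataclasses.asdict(r) for r in self.reports]) \
                .to_csv(out / "pseudogene_reports.tsv", sep="\t", index=False)
            self.control.trials.to_csv(out / "control_trials.tsv",
                                       sep="\t", index=False)
        elif stage == "expression":
            if getattr(self, "bias", None) is not None:
                self.bias.to_csv(out / "homeolog_bias.tsv", sep="\t", index=False)
                pd.DataFrame([dataclasses.asdict(d) for d in self.dominance]) \
                    .to_csv(out / "dominance.tsv", sep="\t", index=False)
        elif stage == "te":
            if getattr(self, "te_summary", None) is not None:
                self.te_summary["composition"].to_csv(
                    out / "te_composition.tsv", sep="\t", index=False)
                self.te_summary["per_chrom"].to_csv(
                    out / "te_specificity_per_chromosome.tsv", sep="\t",
                    index=False)
                pd.DataFrame([
                    {"family_id": f.family_id, "n_copies": f.n_copies,
                     "specificity": f.specificity, **f.copies_per_unit}
                    for f in self.te_summary["families"]]).to_csv(
                        out / "te_families.tsv", sep="\t", index=False)
            if getattr(self, "dated_ltrs", None) is not None:
                pd.DataFrame([dataclasses.asdict(d) for d in self.dated_ltrs]) \
                    .to_csv(out / "dated_ltrs.tsv", sep="\t", index=False)


def math_isnan(x: float) -> bool:
    try:
        return x != x
    except TypeError:
        return False


def run_all(config_path: str | Path, out_dir: str | Path, seed: int = 0,
            stages: Iterable[str] = ALL_STAGES,
            n_trials: int = 1000) -> dict[str, Any]:
    """Convenience wrapper: build a :class:`Pipeline` and run it."""
    return Pipeline(config_path, seed=seed).run_all(out_dir, stages=stages,
                                                    n_trials=n_trials)
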