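"""End-to-end analysis: subsets, rates, distances, indels, tests, structure.

``run_analysis`` composes the library into the full variability-map workflow
and writes a reproducible report bundle of TSV tables (named after the summary
each carries), per-dataset rate tracks, a deletion report, optional structure
files, and a JSON manifest with the resolved configuration. The run is fully
deterministic for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    GroupAssignment,
    MultipleAlignment,
    NON_HYPERVARIABLE,
    RegionSet,
    classify_sites,
    constant_variable_counts,
    gap_statistics,
    read_aligned_fasta,
    read_groups_tsv,
    read_regions_tsv,
    subset_and_compact,
    terminal_gap_mask,
)
from .distances import (
    GTRParams,
    estimate_gtr_params,
    group_summary,
    gtr_distance_matrix,
    overall_summary,
    p_distance_matrix,
)
from .indels import (
    deletion_report,
    deletion_window_from_regions,
    detect_deletion,
    region_indel_summary,
)
from .stattests import run_battery
from .structure import (
    FoldingEngine,
    StructureMap,
    fold_hypervariable_region,
    reference_fold,
    splice,
    write_vienna,
)
from .tiger import SiteRateTable, rate_histogram, rolling_average, summarize_rates, tiger_rates

#: default bracket mode per hypervariable region of the SSU molecule
DEFAULT_BRACKET_MODES = {
    "V1": "internal", "V2": "adjacent", "V3": "artificial", "V4": "adjacent",
    "V5": "adjacent", "V6": "internal", "V7": "internal", "V8": "internal",
    "V9": "adjacent",
}
#: fraction of V4 folded (the 5' portion ahead of its pseudoknots)
V4_FOLD_FRACTION = 0.5


@dataclass
class AnalysisConfig:
    alignment: str
    groups: str
    regions: str
    outdir: str
    coverage_threshold: float = 0.15
    rolling_window: int = 35
    alpha: float = 0.05
    histogram_bin_width: float = 0.05
    outgroup_label: str = "Outgroup"
    deletion_window: tuple[int, int] | None = None   # default: derived from V3
    deletion_tail: int = 14
    deletion_extension: int = 78
    exemplars: dict | None = None                    # clade -> taxon id
    fold_structures: bool = True
    seed: int = 0

    def resolved(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


def fold_exemplar_structure(
    aln: MultipleAlignment,
    taxon: str,
    regions: RegionSet,
    engine: FoldingEngine | None = None,
    bracket_modes: dict | None = None,
) -> tuple[StructureMap, np.ndarray]:
    """Piecewise secondary structure for one exemplar row of the alignment.

    Non-hypervariable segments of the exemplar molecule are folded freely;
    each hypervariable region is folded inside its bracketing stem and spliced
    in. Returns the molecule-coordinate map plus a per-alignment-column
    partner array (-2 = no structural assignment because the exemplar is
    gapped there, -1 = definitely unpaired, otherwise the 0-based partner
    column).
    """
    engine = engine or reference_fold
    modes = {**DEFAULT_BRACKET_MODES, **(bracket_modes or {})}
    row = aln.row(taxon)
    L = aln.length
    mol_cols = [c for c in range(L) if row[c] != "-"]
    molecule = "".join(row[c] for c in mol_cols)
    n = len(molecule)
    labels = regions.labels(L)
    mol_labels = [labels[c] for c in mol_cols]

    # contiguous same-label runs in molecule coordinates
    segments: list[tuple[str, int, int]] = []   # (label, start0, length)
    s = 0
    for i in range(1, n + 1):
        if i == n or mol_labels[i] != mol_labels[s]:
            segments.append((mol_labels[s], s, i - s))
            s = i
    core = StructureMap(molecule, {})
    for label, s0, ln in segments:
        if ln < 8:
            continue
        if label == NON_HYPERVARIABLE:
            sub, _ = engine(molecule[s0 : s0 + ln], None, False)
        else:
            mode = modes.get(label, "internal")
            fold_ln = ln
            if label == "V4":
                fold_ln = max(8, int(np.ceil(ln * V4_FOLD_FRACTION)))
            if mode == "adjacent" and (s0 < 2 or s0 + fold_ln + 2 > n):
                mode = "internal"
            sub = fold_hypervariable_region(molecule, (s0 + 1, fold_ln), mode, engine)
            if fold_ln < ln:   # pad the unfolded 3' remainder as unpaired
                sub = StructureMap(molecule[s0 : s0 + ln],
                                   {i: j for i, j in sub.pair_list()})
        core = splice(core, sub, (s0 + 1, len(sub.seq)))

    partner_col = np.full(L, -2, dtype=int)
    pm = core.partner_array(include_knots=True)
    for mol, col in enumerate(mol_cols):
        partner_col[col] = mol_cols[pm[mol]] if pm[mol] >= 0 else -1
    return core, partner_col


def _rate_outputs(name: str, table: SiteRateTable, outdir: Path,
                  window: int, bin_width: float) -> None:
    table.write_tsv(outdir / f"rates_{name}.tsv", rolling_window=window)
    rate_histogram(table, bin_width).to_csv(
        outdir / f"histogram_{name}.tsv", sep="\t", index=False, na_rep="NA"
    )


def run_analysis(
    config: AnalysisConfig,
    aln: MultipleAlignment | None = None,
    groups: GroupAssignment | None = None,
    regions: RegionSet | None = None,
) -> dict:
    """Run the full analysis; inputs may be passed in memory or read from the
    configured paths. Returns the report bundle (also written to outdir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "config": config.resolved()}
    report: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self.t0, 3),
                    "status": "ok" if exc_type is None else f"failed: {exc}",
                }
                return False
        return _Timer()

    try:
        with stage("inputs"):
            if aln is None:
                aln = read_aligned_fasta(config.alignment)
            if groups is None:
                groups = read_groups_tsv(config.groups)
            if regions is None:
                regions = read_regions_tsv(config.regions)
            groups.validate_for(aln)

        with stage("datasets"):
            rot_taxa = [t for t in aln.ids if groups[t] != config.outgroup_label]
            datasets: dict[str, tuple[MultipleAlignment, RegionSet]] = {}
            if len(rot_taxa) < aln.n_taxa:
                rot_aln, rot_map = subset_and_compact(aln, rot_taxa)
                rot_regions = regions.remap(rot_map)
            else:
                rot_aln, rot_regions = aln, regions
            datasets["all"] = (rot_aln, rot_regions)
            clade_names = [
                lab for lab in groups.labels()
                if lab != config.outgroup_label and len(groups.members(lab)) >= 2
            ]
            for clade in clade_names:
                sub, cmap = subset_and_compact(aln, [
                    t for t in aln.ids if groups[t] == clade
                ])
                datasets[clade] = (sub, regions.remap(cmap))

        with stage("gap_statistics"):
            rows = [{"dataset": "full", **gap_statistics(aln).as_dict()}]
            for name, (sub, _) in datasets.items():
                rows.append({"dataset": name, **gap_statistics(sub).as_dict()})
            gap_table = pd.DataFrame(rows)
            gap_table.to_csv(outdir / "gap_statistics.tsv", sep="\t", index=False)
            report["gap_statistics"] = gap_table

        with stage("distances"):
            pmat = p_distance_matrix(aln)
            gtr_params = estimate_gtr_params(aln)
            gtr_params.to_file(outdir / "gtr_params.tsv")
            gmat = gtr_distance_matrix(aln, gtr_params)
            frames = []
            for mat in (pmat, gmat):
                summ = group_summary(mat, groups)
                summ.insert(0, "model", mat.model)
                frames.append(summ)
                ov = overall_summary(mat, rot_taxa)
                frames.append(pd.DataFrame([{
                    "model": mat.model, "group1": "all-ingroup",
                    "group2": "all-ingroup", **ov,
                }]))
            dist_table = pd.concat(frames, ignore_index=True)
            dist_table.to_csv(outdir / "distance_summary.tsv", sep="\t",
                              index=False, na_rep="n/a", float_format="%.6g")
            pmat.write_tsv(outdir / "p_distances.tsv")
            gmat.write_tsv(outdir / "gtr_distances.tsv")
            report["distance_summary"] = dist_table
            report["p_matrix"], report["gtr_matrix"] = pmat, gmat
            report["gtr_params"] = gtr_params

        with stage("tiger_rates"):
            rate_tables: dict[str, SiteRateTable] = {}
            rows = []
            for name, (sub, sub_regions) in datasets.items():
                table = tiger_rates(sub, config.coverage_threshold)
                rate_tables[name] = table
                _rate_outputs(name, table, outdir, config.rolling_window,
                              config.histogram_bin_width)
                for subset in ("all", "variable_only"):
                    s = summarize_rates(table, subset)
                    rows.append({"dataset": name, "sites": subset,
                                 "mean_rate": s.mean, "se": s.se, "n": s.n})
            rate_summary = pd.DataFrame(rows)
            rate_summary.to_csv(outdir / "rate_summary.tsv", sep="\t",
                                index=False, na_rep="n/a", float_format="%.6g")
            report["rate_summary"] = rate_summary
            report["rate_tables"] = rate_tables

        with stage("site_classes"):
            frames = []
            for name, (sub, sub_regions) in datasets.items():
                counts = constant_variable_counts(
                    rate_tables[name].classification, sub_regions
                )
                counts.insert(0, "dataset", name)
                frames.append(counts)
            class_table = pd.concat(frames, ignore_index=True)
            class_table.to_csv(outdir / "site_classes.tsv", sep="\t", index=False)
            report["site_classes"] = class_table

        with stage("structure"):
            partners: dict[str, np.ndarray] = {}
            if config.fold_structures:
                exemplars = dict(config.exemplars or {})
                for clade in clade_names:
                    exemplars.setdefault(clade, groups.members(clade)[0])
                structures = []
                for name, (sub, sub_regions) in datasets.items():
                    if name == "all":
                        # the pooled set borrows the least-sampled clade's exemplar
                        small = min(clade_names,
                                    key=lambda c: len(groups.members(c)))
                        pool = [t for t in sub.ids]
                        ex = exemplars.get(small, pool[0])
                        if ex not in sub.ids:
                            ex = pool[0]
                    else:
                        ex = exemplars[name] if exemplars[name] in sub.ids else sub.ids[0]
                    smap, partner = fold_exemplar_structure(sub, ex, sub_regions)
                    partners[name] = partner
                    structures.append((f"{name}__{ex}", smap))
                write_vienna(structures, outdir / "structures.vienna")
                report["structures"] = dict(structures)

        with stage("tests"):
            frames = []
            for name, (sub, sub_regions) in datasets.items():
                battery = run_battery(rate_tables[name], sub_regions,
                                      partners.get(name))
                df = pd.DataFrame([r.as_dict() for r in battery])
                df.insert(0, "dataset", name)
                frames.append(df)
            test_table = pd.concat(frames, ignore_index=True)
            test_table.to_csv(outdir / "test_battery.tsv", sep="\t",
                              index=False, na_rep="n/a", float_format="%.6g")
            report["test_battery"] = test_table

        with stage("indels"):
            rot_aln, rot_regions = datasets["all"]
            frames = []
            for clade in clade_names:
                ex = (config.exemplars or {}).get(clade, groups.members(clade)[0])
                if ex not in rot_aln.ids:
                    continue
                summ = region_indel_summary(rot_aln, ex, rot_regions)
                summ.insert(0, "taxon", ex)
                frames.append(summ)
            if frames:
                indel_table = pd.concat(frames, ignore_index=True)
                indel_table.to_csv(outdir / "indel_summary.tsv", sep="\t",
                                   index=False, na_rep="n/a", float_format="%.6g")
                report["indel_summary"] = indel_table
            window = config.deletion_window
            if window is None and "V3" in rot_regions.names():
                window = deletion_window_from_regions(
                    rot_regions, "V3", config.deletion_tail, config.deletion_extension
                )
            if window is not None:
                motifs = detect_deletion(rot_aln, window)
                rep = deletion_report(motifs)
                rep.to_csv(outdir / "deletion_report.tsv", sep="\t", index=False)
                report["deletion_motifs"] = motifs
                report["deletion_report"] = rep
                report["deletion_window"] = window
    finally:
        manifest["config_hash"] = hashlib.sha256(
            json.dumps(config.resolved(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    report["manifest"] = manifest
    report["datasets"] = datasets
    report["groups"] = groups
    return report
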