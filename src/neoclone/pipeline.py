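"""End-to-end orchestration with a reproducible machine-readable report.

``run_pipeline`` sequences the analysis stages — somatic parsing and CCF
estimation, clonal dynamics, expression statistics, candidate
prioritization, FISH quantification — over a cohort directory (the layout
written by :func:`neoclone.cohort_sim.simulate_cohort`) and writes stage
TSVs plus a JSON report.  The report records every threshold in force and
the seed; timestamps are deliberately excluded so an identical config and
seed yields a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from neoclone import __version__, clonal, expression, fish, prioritization, somatic

log = logging.getLogger("neoclone")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths, threshold overrides, responder selection and seed of a run."""

    cohort_dir: str
    out_dir: str
    seed: int = 0
    # thresholds (defaults are the analysis defaults; every value is
    # echoed into the report)
    subclonal_lo: float = 0.1
    subclonal_hi: float = 0.9
    detection_floor: float = 0.1
    stable_delta: float = 0.1
    shift_threshold: float = 0.25
    min_reciprocal_overlap: float = 0.5
    lfc_min: float = 1.0
    fdr_max: float = 0.05
    lcpm_min: float = 3.0
    fish_min_cells: int = 50
    k_max: int = 6
    min_variants_per_sample: int = 5
    responders: list[str] | None = None  # None: pick lowest residual volumes
    n_best_responders: int = 3

    def __post_init__(self):
        if not (0 <= self.subclonal_lo < self.subclonal_hi <= 1):
            raise ValueError("require 0 <= subclonal_lo < subclonal_hi <= 1")
        for name in ("detection_floor", "stable_delta", "shift_threshold",
                     "min_reciprocal_overlap", "fdr_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not Path(self.cohort_dir).is_dir():
            raise FileNotFoundError(f"cohort directory {self.cohort_dir!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def thresholds(self) -> dict:
        skip = {"cohort_dir", "out_dir", "seed", "responders"}
        return {k: v for k, v in dataclasses.asdict(self).items()
                if k not in skip}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        items = sorted(obj) if isinstance(obj, set) else obj
        return [_jsonable(v) for v in items]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = Path(config.cohort_dir)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "stages": {},
    }

    def _fail(stage: str, err: Exception):
        _write_report(report, out)  # preserve partial outputs
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    # ---------------- somatic ---------------- #
    try:
        log.info("stage somatic: reading inputs")
        vcf_dir = cohort / "vcf"
        sheet = somatic.read_sample_sheet(cohort / "samples.csv")
        vcfs = {s: vcf_dir / f"{s}.vcf" for s in sheet["sample"]}
        missing = [s for s, p in vcfs.items() if not p.exists()]
        if missing:
            raise FileNotFoundError(f"missing VCFs for samples {missing}")
        variants, segments, samples = somatic.read_somatic_inputs(
            vcfs, cohort / "segments.tsv", cohort / "samples.csv"
        )
        classified = somatic.classify_segments(
            segments, samples,
            subclonal_lo=config.subclonal_lo,
            subclonal_hi=config.subclonal_hi,
        )
        classified.to_csv(out / "segments_classified.tsv", sep="\t",
                          index=False)
        purity = samples.set_index("sample")["purity"]
        ccf_tables = {
            s: somatic.estimate_ccf_table(
                variants[variants["sample_id"] == s], float(purity[s])
            )
            for s in samples["sample"]
        }
        pd.concat(ccf_tables.values()).to_csv(out / "ccf.tsv", sep="\t",
                                              index=False)
        meta = samples.set_index("sample")
        ff = {}
        ffpe = {}
        for s, tbl in ccf_tables.items():
            if meta.loc[s, "timepoint"] != "BX":
                continue
            v = variants[variants["sample_id"] == s]
            if meta.loc[s, "preservation"] == "FF":
                ff[str(meta.loc[s, "patient"])] = v
            else:
                ffpe[str(meta.loc[s, "patient"])] = v
        ffpe_res = somatic.ffpe_transition_test(ff, ffpe)
        ffpe_res.to_csv(out / "ffpe_test.tsv", sep="\t", index=False)
        report["stages"]["somatic"] = {
            "n_samples": int(len(samples)),
            "n_variants": int(len(variants)),
            "n_segments": int(len(segments)),
            "ffpe_test": _jsonable(ffpe_res),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage-named abort
        _fail("somatic", err)

    # ---------------- clonal dynamics ---------------- #
    try:
        log.info("stage clonal: clustering CCFs and matching timepoints")
        per_patient: dict[str, dict] = {}
        cluster_rows, change_rows, pair_rows = [], [], []
        for patient, grp in samples.groupby("patient"):
            pre_s = grp[(grp["timepoint"] == "BX")
                        & (grp["preservation"] == "FF")]["sample"]
            post_s = grp[grp["timepoint"] == "TX"]["sample"]
            if pre_s.empty or post_s.empty:
                continue
            pre_id, post_id = pre_s.iloc[0], post_s.iloc[0]
            entry: dict = {}
            pre_t, post_t = ccf_tables[pre_id], ccf_tables[post_id]
            if (len(pre_t) >= config.min_variants_per_sample
                    and len(post_t) >= config.min_variants_per_sample):
                pre_cl, _ = clonal.cluster_ccfs(pre_t, k_max=config.k_max,
                                                seed=config.seed)
                post_cl, _ = clonal.cluster_ccfs(post_t, k_max=config.k_max,
                                                 seed=config.seed)
                changes = clonal.match_longitudinal(
                    pre_cl, post_cl, delta=config.stable_delta
                )
                entry["pre_clusters"] = _jsonable(pre_cl)
                entry["post_clusters"] = _jsonable(post_cl)
                entry["changes"] = _jsonable(changes)
                for sid, cl in ((pre_id, pre_cl), (post_id, post_cl)):
                    c = cl.copy()
                    c.insert(0, "sample_id", sid)
                    cluster_rows.append(c)
                ch = changes.copy()
                ch.insert(0, "patient", patient)
                change_rows.append(ch)
            seg_pre = classified[classified["sample_id"] == pre_id]
            seg_post = classified[classified["sample_id"] == post_id]
            if not seg_pre.empty and not seg_post.empty:
                pairs, shift, _kde = clonal.compare_segment_pairs(
                    seg_pre, seg_post,
                    min_reciprocal_overlap=config.min_reciprocal_overlap,
                    ploidy=float(meta.loc[pre_id, "ploidy"]),
                    shift_threshold=config.shift_threshold,
                )
                entry["segment_shift"] = None if np.isnan(shift) else shift
                pr = pairs.copy()
                pr.insert(0, "patient", patient)
                pair_rows.append(pr)
            per_patient[str(patient)] = entry
        for rows, name in ((cluster_rows, "clusters.tsv"),
                           (change_rows, "clonal_changes.tsv"),
                           (pair_rows, "segment_pairs.tsv")):
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / name, sep="\t", index=False
                )
        report["stages"]["clonal"] = {"per_patient": per_patient}
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        _fail("clonal", err)

    # ---------------- expression ---------------- #
    try:
        log.info("stage expression: DE, PCA, junction ratios")
        counts = pd.read_csv(cohort / "counts.tsv", sep="\t",
                             index_col="gene_id")
        groups = meta.loc[counts.columns, "timepoint"]
        de = expression.de_test(counts, groups, treated="TX", control="BX")
        de.to_csv(out / "de.tsv", sep="\t")
        var_frac = expression.pca_variance(counts)
        junctions = pd.read_csv(cohort / "junctions.tsv", sep="\t")
        jr = {}
        for sid, sub in junctions.groupby("sample"):
            reads = sub.set_index("junction_id")["reads"]
            canon = int(reads.filter(like="FL").sum())
            var = int(reads[~reads.index.str.contains("FL")].sum())
            r = expression.junction_ratio(var, canon)
            jr[str(sid)] = {"ratio": r.ratio if r.defined else None,
                            "variant": var, "canonical": canon}
        report["stages"]["expression"] = {
            "n_genes": int(len(counts)),
            "n_tested": int(de["tested"].sum()),
            "n_signif_fdr": int((de["fdr"] < config.fdr_max).sum()),
            "pc_variance_pct": _jsonable(
                np.round(var_frac[:2] * 100, 2)
            ),
            "junction_ratios": _jsonable(jr),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        _fail("expression", err)

    # ---------------- prioritization ---------------- #
    try:
        log.info("stage prioritization: lost-gene overlap and ranking")
        gene_model = pd.read_csv(
            cohort / "genes.bed", sep="\t", header=None,
            names=["chrom", "start", "end", "gene_id"], dtype={"chrom": str},
        )
        lost = prioritization.lost_gene_sets(
            classified, samples, gene_model,
            detection_floor=config.detection_floor,
        )
        if config.responders is not None:
            selected = list(config.responders)
        else:
            vols = samples.groupby("patient")["residual_volume_cc"].first()
            vols = vols[vols.index.isin(lost.keys())]
            selected = list(vols.nsmallest(config.n_best_responders).index)
        overlap = prioritization.overlap_candidates(lost, selected)
        ranked = prioritization.rank_candidates(
            overlap, de, lfc_min=config.lfc_min, fdr_max=config.fdr_max,
            lcpm_min=config.lcpm_min,
        )
        ranked.to_csv(out / "candidates.tsv", sep="\t")
        report["stages"]["prioritization"] = {
            "lost_genes_per_patient": {p: sorted(s) for p, s in lost.items()},
            "selected_responders": selected,
            "overlap": sorted(overlap),
            "ranked_candidates": _jsonable(ranked.reset_index()),
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        _fail("prioritization", err)

    # ---------------- FISH ---------------- #
    try:
        log.info("stage fish: prevalence and response correlation")
        fish_tbl = pd.read_csv(cohort / "fish.tsv", sep="\t")
        summaries = {}
        for sid, sub in fish_tbl.groupby("sample"):
            summaries[str(sid)] = fish.prevalence(
                sub, sample_id=str(sid), min_cells=config.fish_min_cells
            )
        pre_prev, pre_two, volumes = {}, {}, {}
        changes = {}
        for patient, grp in samples.groupby("patient"):
            vol = float(grp["residual_volume_cc"].iloc[0])
            pre_ids = [s for s in grp[grp["timepoint"] == "BX"]["sample"]
                       if s in summaries]
            post_ids = [s for s in grp[grp["timepoint"] == "TX"]["sample"]
                        if s in summaries]
            if pre_ids:
                pre_prev[str(patient)] = summaries[pre_ids[0]].frac_deep_deletion
                pre_two[str(patient)] = summaries[pre_ids[0]].frac_two_plus
                volumes[str(patient)] = vol
            if pre_ids and post_ids:
                changes[str(patient)] = _jsonable(fish.pre_post_change(
                    summaries[pre_ids[0]], summaries[post_ids[0]]
                ))
        corr = {}
        if len(pre_prev) >= 4:
            rho, p = fish.response_correlation(pre_prev, volumes)
            corr["deep_deletion"] = {"rho": rho, "p": p}
            rho2, p2 = fish.response_correlation(pre_two, volumes)
            corr["two_plus"] = {"rho": rho2, "p": p2}
        summary_df = pd.DataFrame([dataclasses.asdict(s)
                                   for s in summaries.values()])
        summary_df.to_csv(out / "fish_summaries.tsv", sep="\t", index=False)
        report["stages"]["fish"] = {
            "per_sample": {
                sid: {"n_cells_pass": s.n_cells_pass,
                      "frac_deep_deletion": s.frac_deep_deletion,
                      "frac_two_plus": s.frac_two_plus,
                      "low_confidence": s.low_confidence}
                for sid, s in summaries.items()
            },
            "response_correlation": _jsonable(corr),
            "pre_post_change": changes,
        }
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        _fail("fish", err)

    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    payload = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(payload + "\n")


def analyze_cohort(
    cohort,
    responders: list[str] | None = None,
    n_best_responders: int = 3,
    detection_floor: float = 0.1,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    lcpm_min: float = 3.0,
    fish_min_cells: int = 50,
) -> dict:
    """In-memory prioritization + FISH analysis of a simulated cohort.

    Runs the file-free core of the pipeline on a
    :class:`neoclone.cohort_sim.Cohort`: segment classification, per-patient
    lost-gene sets, the cross-responder overlap, expression-filtered ranking,
    and the FISH prevalence vs residual-volume correlation.  Used for
    replicated planted-truth evaluation where file round-trips would
    dominate the cost.
    """
    classified = somatic.classify_segments(cohort.segments, cohort.samples)
    lost = prioritization.lost_gene_sets(
        classified, cohort.samples, cohort.gene_model,
        detection_floor=detection_floor,
    )
    if responders is None:
        vols = cohort.samples.groupby("patient")["residual_volume_cc"].first()
        vols = vols[vols.index.isin(lost.keys())]
        responders = list(vols.nsmallest(n_best_responders).index)
    overlap = prioritization.overlap_candidates(lost, responders)
    meta = cohort.samples.set_index("sample")
    groups = meta.loc[cohort.counts.columns, "timepoint"]
    de = expression.de_test(cohort.counts, groups, treated="TX", control="BX")
    ranked = prioritization.rank_candidates(
        overlap, de, lfc_min=lfc_min, fdr_max=fdr_max, lcpm_min=lcpm_min
    )
    pre_prev, volumes = {}, {}
    for sid, sub in cohort.fish.groupby("sample"):
        if sid not in meta.index or meta.loc[sid, "timepoint"] != "BX":
            continue
        patient = str(meta.loc[sid, "patient"])
        summ = fish.prevalence(sub, sample_id=str(sid),
                               min_cells=fish_min_cells)
        pre_prev[patient] = summ.frac_deep_deletion
        volumes[patient] = float(meta.loc[sid, "residual_volume_cc"])
    rho = p = float("nan")
    if len(pre_prev) >= 4:
        rho, p = fish.response_correlation(pre_prev, volumes)
    return {
        "classified": classified,
        "lost": lost,
        "responders": responders,
        "overlap": overlap,
        "de": de,
        "ranked": ranked,
        "fish_prevalence": pre_prev,
        "fish_rho": rho,
        "fish_p": p,
    }
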