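"""Candidate-gene prioritization from treatment-depleted subclonal losses.

The central integration step: per patient, the set of genes under a
*subclonal* copy-number loss before treatment that is no longer detectable
in the residual tumor; the strict intersection of those sets across the
selected best-responding patients; and an expression-based ranking of the
intersection (overexpression after treatment suggests the gene's loss
marked the treatment-sensitive population).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from neoclone.expression import filter_candidates

DETECTION_FLOOR = 0.1  # cn_fraction at or below this is "not detectable"
QUALIFYING_CLASSES = frozenset({"subclonal", "rescued-subclonal"})


class ExcludedSampleError(ValueError):
    """A sample with an unclear purity/ploidy solution cannot be used."""


def _overlapping_genes(segments: pd.DataFrame,
                       gene_model: pd.DataFrame) -> set[str]:
    """Gene ids overlapped (>= 1 bp) by any segment in the table."""
    hits: set[str] = set()
    for chrom, seg_c in segments.groupby(segments["chrom"].astype(str)):
        genes_c = gene_model[gene_model["chrom"].astype(str) == chrom]
        if genes_c.empty:
            continue
        gs = genes_c["start"].to_numpy()
        ge = genes_c["end"].to_numpy()
        for seg in seg_c.itertuples(index=False):
            ov = (gs < seg.end) & (ge > seg.start)
            hits.update(genes_c["gene_id"].to_numpy()[ov])
    return hits


def lost_genes_per_patient(
    pre_segments: pd.DataFrame,
    post_segments: pd.DataFrame,
    gene_model: pd.DataFrame,
    detection_floor: float = DETECTION_FLOOR,
) -> set[str]:
    """Genes lost subclonally pre-treatment and undetectable post-treatment.

    Both segment tables must carry ``seg_class`` and ``is_loss`` columns
    (see :func:`neoclone.somatic.classify_segments`).  A gene qualifies iff
    at least one pre-treatment loss segment of class subclonal or
    rescued-subclonal overlaps it by >= 1 bp AND no post-treatment loss
    segment with cn_fraction above the detection floor overlaps it.

    Raises :class:`ExcludedSampleError` when either timepoint contains
    segments from a purity-excluded sample.
    """
    for name, seg in (("pre", pre_segments), ("post", post_segments)):
        if (seg["seg_class"] == "excluded").any():
            raise ExcludedSampleError(
                f"{name}-treatment sample excluded for unclear purity/ploidy"
            )
    if not {"seg_class", "is_loss"} <= set(pre_segments.columns):
        raise ValueError("segments must be classified first")

    pre_loss = pre_segments[
        pre_segments["is_loss"]
        & pre_segments["seg_class"].isin(QUALIFYING_CLASSES)
    ]
    post_loss = post_segments[
        post_segments["is_loss"]
        & (post_segments["cn_fraction"] > detection_floor)
    ]
    candidates = _overlapping_genes(pre_loss, gene_model)
    still_lost = _overlapping_genes(post_loss, gene_model)
    return candidates - still_lost


def lost_gene_sets(
    classified_segments: pd.DataFrame,
    samples: pd.DataFrame,
    gene_model: pd.DataFrame,
    detection_floor: float = DETECTION_FLOOR,
) -> dict[str, set[str]]:
    """Per-patient lost-gene sets over a whole classified cohort.

    Pre-treatment (BX) segments are pooled across aliquots of the biopsy;
    patients lacking either timepoint, or with purity-excluded samples, are
    skipped with a warning.
    """
    meta = samples.set_index("sample")
    seg = classified_segments.copy()
    seg["patient"] = seg["sample_id"].map(meta["patient"])
    seg["timepoint"] = seg["sample_id"].map(meta["timepoint"])
    out: dict[str, set[str]] = {}
    for patient, seg_p in seg.groupby("patient"):
        pre = seg_p[seg_p["timepoint"] == "BX"]
        post = seg_p[seg_p["timepoint"] == "TX"]
        if pre.empty or post.empty:
            warnings.warn(f"patient {patient}: missing a timepoint; skipped")
            continue
        try:
            out[str(patient)] = lost_genes_per_patient(
                pre, post, gene_model, detection_floor=detection_floor
            )
        except ExcludedSampleError:
            warnings.warn(
                f"patient {patient}: unclear purity/ploidy sample; skipped"
            )
    return out


def overlap_candidates(
    per_patient: Mapping[str, set[str]],
    patients: Iterable[str],
) -> set[str]:
    """Strict intersection of lost-gene sets across the selected patients."""
    patients = list(patients)
    if not patients:
        raise ValueError("no patients selected for the overlap")
    missing = [p for p in patients if p not in per_patient]
    if missing:
        raise KeyError(f"no lost-gene set computed for patients {missing}")
    result = set(per_patient[patients[0]])
    for p in patients[1:]:
        result &= per_patient[p]
    return result


def rank_candidates(
    candidates: Iterable[str],
    de_results: pd.DataFrame,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
    lcpm_min: float = 3.0,
) -> pd.DataFrame:
    """Expression-filter and rank overlap candidates.

    Candidates passing the overexpression filter (strict logFC > ``lfc_min``,
    FDR < ``fdr_max``, logCPM > ``lcpm_min``) are ranked by descending logFC
    with ties broken by ascending FDR.  Candidates absent from the DE gene
    universe are retained with missing statistics and ranked last, with a
    warning.
    """
    candidates = sorted(set(candidates))
    in_universe = [g for g in candidates if g in de_results.index]
    absent = [g for g in candidates if g not in de_results.index]
    if absent:
        warnings.warn(
            f"{len(absent)} candidate(s) absent from the DE universe; "
            "retained without statistics and ranked last"
        )
    de_sub = de_results.loc[in_universe]
    survivors = filter_candidates(de_sub, lfc_min, fdr_max, lcpm_min)
    ranked = de_sub.loc[survivors, ["logFC", "logCPM", "p", "fdr"]].copy()
    ranked = ranked.sort_values(["logFC", "fdr"], ascending=[False, True])
    if absent:
        tail = pd.DataFrame(np.nan, index=pd.Index(absent),
                            columns=["logFC", "logCPM", "p", "fdr"])
        ranked = pd.concat([ranked, tail])
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    ranked.index.name = "gene_id"
    return ranked
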