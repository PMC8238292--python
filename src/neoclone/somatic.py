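"""Somatic input parsing, CCF estimation, subclonality classes, FFPE test.

The cancer cell fraction (CCF) of an SNV is recovered from its variant
allele frequency (VAF) with the standard purity / copy-number
transformation.  With tumor purity ``rho``, local tumor total copy number
``CNt`` and mutation multiplicity ``m`` (mutated copies per mutated cell),

    E[VAF] = rho * m * CCF / (rho * CNt + (1 - rho) * 2)

so ``CCF = VAF * (rho * CNt + (1 - rho) * 2) / (rho * m)`` with ``m``
estimated by rounding the same expression evaluated at CCF = 1 and clipping
to ``[1, major_cn]``.

Copy-number segments are classified from their copy-number fraction (the
fraction of tumor cells bearing the aberration): clonal at >= 0.9,
subclonal strictly between 0.1 and 0.9, and a loss at <= 0.1 is *rescued*
as subclonal only when the same loss is present at > 0.1 in at least one
other sample of the patient.  Samples with unclear purity/ploidy solutions
are excluded.

The FFPE artifact test compares, per matched fresh-frozen / FFPE pair, the
fraction of C>T / G>A calls (the strand-collapsed cytosine-deamination
signature) within low-VAF bins, with a one-sided paired t-test
(alternative: FFPE enriched).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

SUBCLONAL_LO = 0.1
SUBCLONAL_HI = 0.9
MAX_ALLELIC_COPIES = 4  # above this a gain is never treated as a driver

VAF_BINS_DEFAULT = ((0.01, 0.10), (0.10, 0.25))


@dataclass(frozen=True)
class VariantCall:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    sample_id: str = ""

    def __post_init__(self):
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be >= 0")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        if self.depth == 0:
            raise ValueError("VAF undefined at zero depth")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class SegmentCall:
    chrom: str
    start: int  # 0-based half-open
    end: int
    major_cn: int
    minor_cn: int
    cn_fraction: float
    sample_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start >= end ({self.start} >= {self.end})")
        if self.major_cn < 0 or self.minor_cn < 0:
            raise ValueError("allele copy numbers must be >= 0")
        if not 0.0 <= self.cn_fraction <= 1.0:
            raise ValueError("cn_fraction must be in [0, 1]")

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0


@dataclass(frozen=True)
class SampleMeta:
    patient: str
    sample: str
    timepoint: str  # BX (pre) / TX (post)
    preservation: str  # FF / FFPE
    purity: float
    ploidy: float
    purity_clear: bool = True
    residual_volume_cc: float = float("nan")
    response: str = ""

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class CCFEstimate:
    variant: VariantCall
    multiplicity: int
    ccf: float
    ci_low: float
    ci_high: float
    flagged: bool  # unclipped CCF exceeded 1


# --------------------------------------------------------------------- #
# input parsing                                                         #
# --------------------------------------------------------------------- #

def read_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read one single-sample VCF into a variants table with AD-based counts."""
    path = str(path)
    vcf = VCF(path)
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else Path(path).stem
    rows = []
    for i, v in enumerate(vcf):
        try:
            ad = v.format("AD")
            dp = v.format("DP")
        except KeyError as err:  # field absent from the header
            raise ValueError(
                f"{path}: record {i + 1} lacks FORMAT field {err}"
            ) from err
        if ad is None:
            raise ValueError(f"{path}: record {i + 1} has no AD FORMAT field")
        if dp is None:
            raise ValueError(f"{path}: record {i + 1} has no DP FORMAT field")
        ref_ct, alt_ct = int(ad[0][0]), int(ad[0][1])
        rows.append((sample_id, v.CHROM, v.POS, v.REF, v.ALT[0], ref_ct, alt_ct))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt",
                 "ref_count", "alt_count"],
    )


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a copy-number segment TSV (Battenberg-style dialect)."""
    seg = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["sample_id", "chrom", "start", "end", "major_cn", "minor_cn",
                "cn_fraction"]
    missing = [c for c in required if c not in seg.columns]
    if missing:
        raise ValueError(f"{path}: missing segment columns {missing}")
    bad = seg.index[seg["start"] >= seg["end"]]
    if len(bad):
        raise ValueError(
            f"{path}: segment start >= end at line {int(bad[0]) + 2}"
        )
    if ((seg["cn_fraction"] < 0) | (seg["cn_fraction"] > 1)).any():
        raise ValueError(f"{path}: cn_fraction outside [0, 1]")
    return seg


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    required = ["patient", "sample", "timepoint", "preservation", "purity",
                "ploidy", "purity_clear"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"{path}: missing sample-sheet columns {missing}")
    if ((sheet["purity"] <= 0) | (sheet["purity"] > 1)).any():
        raise ValueError(f"{path}: purity outside (0, 1]")
    return sheet


def annotate_variants(variants: pd.DataFrame,
                      segments: pd.DataFrame) -> pd.DataFrame:
    """Attach each variant's overlapping copy-number segment (same sample).

    Adds ``major_cn``, ``minor_cn``, ``cn_fraction`` and ``in_segment``;
    variants outside any segment get NaN copy state and ``in_segment=False``.
    """
    out = variants.copy()
    out["major_cn"] = np.nan
    out["minor_cn"] = np.nan
    out["cn_fraction"] = np.nan
    out["in_segment"] = False
    for (sample, chrom), idx in out.groupby(
        ["sample_id", "chrom"], sort=False
    ).groups.items():
        seg = segments[(segments["sample_id"] == sample)
                       & (segments["chrom"].astype(str) == str(chrom))]
        if seg.empty:
            continue
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        pos0 = out.loc[idx, "pos"].to_numpy() - 1  # to 0-based
        j = np.searchsorted(starts, pos0, side="right") - 1
        ok = (j >= 0) & (pos0 < ends[np.clip(j, 0, len(ends) - 1)])
        hit = idx[ok]
        out.loc[hit, "major_cn"] = seg["major_cn"].to_numpy()[j[ok]]
        out.loc[hit, "minor_cn"] = seg["minor_cn"].to_numpy()[j[ok]]
        out.loc[hit, "cn_fraction"] = seg["cn_fraction"].to_numpy()[j[ok]]
        out.loc[hit, "in_segment"] = True
    return out


def read_somatic_inputs(
    vcf_paths: Mapping[str, str | Path] | Iterable[str | Path],
    segments_path: str | Path,
    sample_sheet_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read VCFs, a segment TSV and the sample sheet.

    Returns ``(variants, segments, samples)``; variants are annotated with
    their overlapping segment's copy state.
    """
    if isinstance(vcf_paths, Mapping):
        frames = [read_vcf(p, sample_id=s) for s, p in vcf_paths.items()]
    else:
        frames = [read_vcf(p) for p in vcf_paths]
    variants = (
        pd.concat(frames, ignore_index=True) if frames
        else pd.DataFrame(columns=["sample_id", "chrom", "pos", "ref", "alt",
                                   "ref_count", "alt_count"])
    )
    segments = read_segments(segments_path)
    samples = read_sample_sheet(sample_sheet_path)
    variants = annotate_variants(variants, segments)
    return variants, segments, samples


# --------------------------------------------------------------------- #
# CCF estimation                                                        #
# --------------------------------------------------------------------- #

def estimate_ccf(variant: VariantCall, segment: SegmentCall,
                 purity: float) -> CCFEstimate:
    """Cancer-cell-fraction estimate for one SNV given its copy segment."""
    if purity <= 0:
        raise ValueError("purity must be > 0")
    if variant.depth == 0:
        raise ValueError("CCF undefined at zero depth")
    cnt = segment.total_cn
    if segment.major_cn == 0:
        raise ValueError(
            "CCF undefined on a segment with zero tumor copies (CNt = 0)"
        )
    vaf = variant.vaf
    denom_factor = purity * cnt + (1.0 - purity) * 2.0
    m = int(np.clip(round(vaf * denom_factor / purity), 1, segment.major_cn))
    raw = vaf * denom_factor / (purity * m)
    lo, hi = proportion_confint(variant.alt_count, variant.depth,
                                alpha=0.05, method="wilson")
    scale = denom_factor / (purity * m)
    return CCFEstimate(
        variant=variant,
        multiplicity=m,
        ccf=float(np.clip(raw, 0.0, 1.5)),
        ci_low=float(np.clip(lo * scale, 0.0, 1.5)),
        ci_high=float(np.clip(hi * scale, 0.0, 1.5)),
        flagged=raw > 1.0,
    )


def estimate_ccf_table(variants: pd.DataFrame, purity: float) -> pd.DataFrame:
    """Vectorized CCF estimation over an annotated variants table."""
    v = variants[variants["in_segment"]
                 & (variants["ref_count"] + variants["alt_count"] > 0)
                 & (variants["major_cn"] > 0)].copy()
    depth = (v["ref_count"] + v["alt_count"]).to_numpy(float)
    vaf = v["alt_count"].to_numpy(float) / depth
    cnt = (v["major_cn"] + v["minor_cn"]).to_numpy(float)
    denom = purity * cnt + (1 - purity) * 2.0
    m = np.clip(np.round(vaf * denom / purity), 1,
                v["major_cn"].to_numpy(float))
    raw = vaf * denom / (purity * m)
    lo, hi = proportion_confint(v["alt_count"], depth.astype(int),
                                alpha=0.05, method="wilson")
    scale = denom / (purity * m)
    v["vaf"] = vaf
    v["multiplicity"] = m.astype(int)
    # expected VAF per unit CCF; the binomial-mixture clustering's forward map
    v["p_per_ccf"] = purity * m / denom
    v["ccf"] = np.clip(raw, 0.0, 1.5)
    v["ccf_ci_low"] = np.clip(np.asarray(lo) * scale, 0.0, 1.5)
    v["ccf_ci_high"] = np.clip(np.asarray(hi) * scale, 0.0, 1.5)
    v["ccf_flagged"] = raw > 1.0
    return v


# --------------------------------------------------------------------- #
# segment subclonality classes                                          #
# --------------------------------------------------------------------- #

def is_loss(major_cn: int, minor_cn: int, sample_ploidy: float) -> bool:
    """Loss iff total copies below rounded ploidy, or LOH (minor = 0)."""
    return (major_cn + minor_cn) < round(sample_ploidy) or minor_cn == 0


def classify_segment(
    segment: SegmentCall,
    sample_ploidy: float,
    patient_segments: Iterable[SegmentCall] = (),
    purity_clear: bool = True,
    subclonal_lo: float = SUBCLONAL_LO,
    subclonal_hi: float = SUBCLONAL_HI,
) -> str:
    """Subclonality class of one segment.

    Returns one of ``clonal`` (cn_fraction >= 0.9), ``subclonal``
    (0.1 < fraction < 0.9), ``rescued-subclonal`` (a loss at fraction <= 0.1
    that is present at > 0.1 in >= 1 other sample of the patient),
    ``absent`` (fraction <= 0.1, not rescued) or ``excluded`` (unclear
    purity/ploidy sample).
    """
    if not purity_clear:
        return "excluded"
    f = segment.cn_fraction
    if f >= subclonal_hi:
        return "clonal"
    if f > subclonal_lo:
        return "subclonal"
    if is_loss(segment.major_cn, segment.minor_cn, sample_ploidy):
        for other in patient_segments:
            if other.sample_id == segment.sample_id:
                continue
            if other.chrom != segment.chrom:
                continue
            if other.start >= segment.end or other.end <= segment.start:
                continue
            if (other.cn_fraction > subclonal_lo
                    and is_loss(other.major_cn, other.minor_cn, sample_ploidy)):
                return "rescued-subclonal"
    return "absent"


def classify_segments(segments: pd.DataFrame,
                      samples: pd.DataFrame,
                      subclonal_lo: float = SUBCLONAL_LO,
                      subclonal_hi: float = SUBCLONAL_HI) -> pd.DataFrame:
    """Classify every segment of every sample; adds ``seg_class``/``is_loss``.

    ``samples`` supplies per-sample ploidy, the patient grouping used by the
    low-fraction rescue rule, and the unclear-purity exclusion flag.
    """
    meta = samples.set_index("sample")
    out = segments.copy()
    out["is_loss"] = [
        is_loss(r.major_cn, r.minor_cn, meta.loc[r.sample_id, "ploidy"])
        for r in out.itertuples(index=False)
    ]
    classes = []
    patient_of = meta["patient"]
    seg_objs = [
        SegmentCall(str(r.chrom), int(r.start), int(r.end), int(r.major_cn),
                    int(r.minor_cn), float(r.cn_fraction), str(r.sample_id))
        for r in out.itertuples(index=False)
    ]
    by_patient: dict[str, list[SegmentCall]] = {}
    for s in seg_objs:
        by_patient.setdefault(str(patient_of[s.sample_id]), []).append(s)
    for s in seg_objs:
        classes.append(classify_segment(
            s,
            sample_ploidy=float(meta.loc[s.sample_id, "ploidy"]),
            patient_segments=by_patient[str(patient_of[s.sample_id])],
            purity_clear=bool(meta.loc[s.sample_id, "purity_clear"]),
            subclonal_lo=subclonal_lo,
            subclonal_hi=subclonal_hi,
        ))
    out["seg_class"] = classes
    return out


# --------------------------------------------------------------------- #
# FFPE artifact test                                                    #
# --------------------------------------------------------------------- #

def _transition_fraction(df: pd.DataFrame, lo: float, hi: float) -> float | None:
    """Fraction of C>T / G>A calls among SNVs with VAF in [lo, hi)."""
    depth = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        vaf = df["alt_count"] / depth.replace(0, np.nan)
    in_bin = (vaf >= lo) & (vaf < hi)
    n = int(in_bin.sum())
    if n == 0:
        return None
    sub = df[in_bin]
    deam = ((sub["ref"] == "C") & (sub["alt"] == "T")) | (
        (sub["ref"] == "G") & (sub["alt"] == "A")
    )
    return float(deam.mean())


def ffpe_transition_test(
    ff_variants: Mapping[str, pd.DataFrame],
    ffpe_variants: Mapping[str, pd.DataFrame],
    vaf_bins: tuple = VAF_BINS_DEFAULT,
) -> pd.DataFrame:
    """Paired test of C>T / G>A enrichment in FFPE vs FF aliquots.

    ``ff_variants`` / ``ffpe_variants`` map patient id to that patient's
    variants table; patients present in both are used.  Per patient and VAF
    bin the deamination-signature fraction is computed; a one-sided paired
    t-test (alternative: FFPE > FF) is run per bin.  Patients with no SNV in
    a bin on either side are dropped from that bin with a warning; when all
    paired differences are zero, p = 1 by convention.
    """
    patients = sorted(set(ff_variants) & set(ffpe_variants))
    if len(patients) < 2:
        raise ValueError("need >= 2 matched FF/FFPE pairs")
    rows = []
    for lo, hi in vaf_bins:
        ff_fr, ffpe_fr = [], []
        for p in patients:
            a = _transition_fraction(ff_variants[p], lo, hi)
            b = _transition_fraction(ffpe_variants[p], lo, hi)
            if a is None or b is None:
                warnings.warn(
                    f"patient {p}: no SNVs in VAF bin [{lo}, {hi}); "
                    "pair dropped from this bin"
                )
                continue
            ff_fr.append(a)
            ffpe_fr.append(b)
        n = len(ff_fr)
        if n < 2:
            rows.append((f"[{lo},{hi})", n, np.nan, np.nan))
            continue
        diff = np.asarray(ffpe_fr) - np.asarray(ff_fr)
        if np.allclose(diff, 0.0):
            p_val = 1.0
        else:
            p_val = float(stats.ttest_rel(
                ffpe_fr, ff_fr, alternative="greater"
            ).pvalue)
            if np.isnan(p_val):  # zero variance, nonzero mean difference
                p_val = 0.0 if diff.mean() > 0 else 1.0
        rows.append((f"[{lo},{hi})", n, float(diff.mean()), p_val))
    return pd.DataFrame(
        rows, columns=["vaf_bin", "n_pairs", "mean_diff", "p_value"]
    )
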