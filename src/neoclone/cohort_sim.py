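"""Synthetic longitudinal tumor cohort generator.

Emulates the data structure of a neoadjuvant ADT trial cohort so every
downstream stage is testable without controlled-access sequencing data:

* paired pre-treatment (BX) and post-treatment (TX) samples per patient, the
  biopsy split into a fresh-frozen (FF) and an FFPE aliquot;
* clonal/subclonal SNV VAF structure under purity and local copy number
  (binomial reads at Poisson depth);
* allele-specific copy-number loss segments, including a planted subclonal
  deep deletion over a designated "sensitivity gene" that is depleted by
  treatment in responders;
* FFPE deamination artifacts as extra low-VAF C>T / G>A calls;
* negative-binomial expression counts with a planted overexpression
  signature (treated vs untreated);
* per-cell FISH signal counts whose deep-deletion fraction drives a
  monotonically decreasing residual-tumor-volume model.

The generator returns an in-memory :class:`Cohort` (DataFrames plus a
:class:`GroundTruth`) and can serialize it to the plain-text formats the
analysis modules consume (VCF v4.2, TSV, BED, CSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.array(["A", "C", "G", "T"])
_GENE_LENGTH = 10_000
_GENE_SPACING = 100_000
_N_CHROMS = 4
_LOSS_PAD = 20_000  # loss segments extend this far beyond the hit gene


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Fractions are in [0, 1]; ranges are (low, high) with low <= high.
    ``ffpe_artifact_rate`` is the expected number of artifact calls per true
    SNV in an FFPE aliquot; ``de_logfc`` is the planted log2 fold change of
    the differentially expressed genes (treated vs untreated);
    ``dispersion`` is the negative-binomial dispersion (var = mu + d*mu^2).
    """

    n_patients: int = 12
    clones_per_tumor: tuple[int, int] = (2, 3)
    purity_range: tuple[float, float] = (0.4, 0.8)
    mean_depth: float = 200.0
    n_snvs_per_patient: int = 60
    n_genes: int = 200
    planted_gene_id: str = "G0100"
    deep_del_prevalence_range: tuple[float, float] = (0.05, 0.45)
    ffpe_artifact_rate: float = 0.5
    de_logfc: float = 2.0
    dispersion: float = 0.1
    seed: int = 0
    # secondary knobs (defaults emulate the study design)
    n_de_genes: int = 20
    n_best_responders: int = 3
    fish_cells_per_sample: int = 500
    volume_max_cc: float = 10.0
    volume_exponent: float = 3.0
    volume_noise_sd: float = 0.25
    ffpe_vaf_range: tuple[float, float] = (0.01, 0.10)
    frac_unclear_purity: float = 0.0
    # fraction of SNVs in the low-frequency subclonal tail (CCF ~ U(0.02, 0.3))
    # rather than in a discrete clone; emulates the continuous low-VAF tail of
    # real somatic spectra and keeps the low-VAF bins populated in every sample
    snv_tail_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        for name in ("clones_per_tumor", "purity_range",
                     "deep_del_prevalence_range", "ffpe_vaf_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"degenerate range for {name}: min > max")
        p_lo, p_hi = self.purity_range
        if not (0.0 < p_lo and p_hi <= 1.0):
            raise ValueError("purity_range must lie in (0, 1]")
        for name in ("deep_del_prevalence_range", "ffpe_vaf_range"):
            lo, hi = getattr(self, name)
            if lo < 0.0 or hi > 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.ffpe_artifact_rate < 0:
            raise ValueError("ffpe_artifact_rate must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.n_genes > 0 and self.planted_gene_id not in set(
            _gene_ids(self.n_genes)
        ):
            raise ValueError(
                f"planted_gene_id {self.planted_gene_id!r} does not index a "
                f"simulated gene (n_genes={self.n_genes})"
            )
        if self.n_best_responders > max(self.n_patients, 0) and self.n_patients > 0:
            raise ValueError("n_best_responders exceeds n_patients")


@dataclass
class GroundTruth:
    """Planted truth of a simulated cohort."""

    clone_ccfs_pre: dict[str, np.ndarray] = field(default_factory=dict)
    clone_ccfs_post: dict[str, np.ndarray] = field(default_factory=dict)
    planted_loss_pre: dict[str, bool] = field(default_factory=dict)
    planted_loss_post: dict[str, bool] = field(default_factory=dict)
    de_status: dict[str, float] = field(default_factory=dict)  # gene -> true logFC
    deep_del_prevalence: dict[str, float] = field(default_factory=dict)  # sample ->
    residual_volume_cc: dict[str, float] = field(default_factory=dict)  # patient ->
    best_responders: list[str] = field(default_factory=list)


@dataclass
class Cohort:
    """In-memory synthetic cohort: tables plus ground truth.

    ``variants`` has one row per called SNV per sample
    (sample_id, chrom, pos, ref, alt, ref_count, alt_count);
    ``segments`` one row per copy-number segment per sample
    (sample_id, chrom, start, end, major_cn, minor_cn, cn_fraction),
    half-open 0-based intervals; ``counts`` is genes x samples;
    ``samples`` is the clinical sample sheet.
    """

    config: SimConfig
    samples: pd.DataFrame
    variants: pd.DataFrame
    segments: pd.DataFrame
    gene_model: pd.DataFrame
    counts: pd.DataFrame
    junctions: pd.DataFrame
    fish: pd.DataFrame
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> dict[str, object]:
        """Serialize all tables to ``out_dir``; returns the path manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vcf_dir = out / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        vcf_paths: dict[str, str] = {}
        for sample_id in self.samples["sample"]:
            sub = self.variants[self.variants["sample_id"] == sample_id]
            path = vcf_dir / f"{sample_id}.vcf"
            _write_vcf(path, sample_id, sub)
            vcf_paths[sample_id] = str(path)
        self.segments.to_csv(out / "segments.tsv", sep="\t", index=False)
        bed = self.gene_model[["chrom", "start", "end", "gene_id"]]
        bed.to_csv(out / "genes.bed", sep="\t", index=False, header=False)
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene_id")
        self.junctions.to_csv(out / "junctions.tsv", sep="\t", index=False)
        self.fish.to_csv(out / "fish.tsv", sep="\t", index=False)
        self.samples.to_csv(out / "samples.csv", index=False)
        return {
            "vcf": vcf_paths,
            "segments": str(out / "segments.tsv"),
            "gene_model": str(out / "genes.bed"),
            "counts": str(out / "counts.tsv"),
            "junctions": str(out / "junctions.tsv"),
            "fish": str(out / "fish.tsv"),
            "samples": str(out / "samples.csv"),
        }


def _gene_ids(n_genes: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n_genes)]


def make_gene_model(n_genes: int) -> pd.DataFrame:
    """Gene intervals on a toy genome: 4 chromosomes, evenly spaced genes."""
    per_chrom = -(-n_genes // _N_CHROMS) if n_genes else 0
    rows = []
    for i, gid in enumerate(_gene_ids(n_genes)):
        chrom = str(i // per_chrom + 1)
        j = i % per_chrom
        start = 50_000 + j * _GENE_SPACING
        rows.append((chrom, start, start + _GENE_LENGTH, gid))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def chrom_lengths(n_genes: int) -> dict[str, int]:
    per_chrom = -(-n_genes // _N_CHROMS) if n_genes else 0
    length = 50_000 + per_chrom * _GENE_SPACING + 50_000
    return {str(c + 1): length for c in range(_N_CHROMS)}


def classify_response(
    residual_volume_cc: float,
    max_gleason: int | None = None,
    any_tumor: bool = True,
    involution: bool = False,
) -> str:
    """Pathologic response category from residual tumor volume.

    CR (complete response, ypT0) iff no identifiable tumor; MRD (minimal
    residual disease) iff residual volume <= 0.2 cc with no high-grade
    elements (Gleason score <= 3+3 = 6); otherwise PR or NR by the
    histologic-involution flag.
    """
    if residual_volume_cc < 0:
        raise ValueError("residual volume must be >= 0")
    if not any_tumor:
        return "CR"
    if residual_volume_cc <= 0.2 and (max_gleason is None or max_gleason <= 6):
        return "MRD"
    return "PR" if involution else "NR"


def _draw_reads(rng, ccf, purity, mean_depth, cn_total=2, multiplicity=1):
    """Binomial alt reads at Poisson depth under the standard VAF map."""
    p = purity * multiplicity * ccf / (purity * cn_total + (1 - purity) * 2)
    depth = rng.poisson(mean_depth, size=np.shape(ccf))
    depth = np.maximum(depth, 1)
    alt = rng.binomial(depth, np.clip(p, 0.0, 1.0))
    return depth - alt, alt


def _write_vcf(path: Path, sample_id: str, variants: pd.DataFrame) -> None:
    lines = ["##fileformat=VCFv4.2", "##source=neoclone.cohort_sim"]
    for chrom in map(str, range(1, _N_CHROMS + 1)):
        lines.append(f"##contig=<ID={chrom}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
    ]
    sub = variants.sort_values(["chrom", "pos"], kind="mergesort")
    for row in sub.itertuples(index=False):
        dp = int(row.ref_count + row.alt_count)
        lines.append(
            f"{row.chrom}\t{int(row.pos)}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t."
            f"\tGT:AD:DP\t0/1:{int(row.ref_count)},{int(row.alt_count)}:{dp}"
        )
    path.write_text("\n".join(lines) + "\n")


def _empty_cohort(config: SimConfig) -> Cohort:
    samples = pd.DataFrame(
        columns=["patient", "sample", "timepoint", "preservation", "purity",
                 "ploidy", "purity_clear", "residual_volume_cc", "response"]
    )
    variants = pd.DataFrame(
        columns=["sample_id", "chrom", "pos", "ref", "alt", "ref_count", "alt_count"]
    )
    segments = pd.DataFrame(
        columns=["sample_id", "chrom", "start", "end", "major_cn", "minor_cn",
                 "cn_fraction"]
    )
    junctions = pd.DataFrame(columns=["junction_id", "sample", "reads"])
    fish = pd.DataFrame(
        columns=["sample", "cell_id", "target_signals", "centromere_signals"]
    )
    gene_model = make_gene_model(config.n_genes)
    counts = pd.DataFrame(index=pd.Index(gene_model["gene_id"], name="gene_id"))
    return Cohort(config, samples, variants, segments, gene_model, counts,
                  junctions, fish, GroundTruth())


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None):
    """Generate a synthetic cohort; optionally write it to ``out_dir``.

    Returns the :class:`Cohort`; when ``out_dir`` is given, also writes the
    VCF/TSV/BED/CSV files and attaches the path manifest as
    ``cohort.paths``.  Identical configs (same seed) produce byte-identical
    outputs.
    """
    rng = np.random.default_rng(config.seed)
    gene_model = make_gene_model(config.n_genes)
    clens = chrom_lengths(config.n_genes)

    if config.n_patients == 0:
        cohort = _empty_cohort(config)
        if out_dir is not None:
            cohort.paths = cohort.write(out_dir)
        return cohort

    patients = [f"P{i + 1:02d}" for i in range(config.n_patients)]
    truth = GroundTruth()

    # ------------------------------------------------------------------ #
    # Response axis: deep-deletion prevalence -> residual volume (+noise) #
    # ------------------------------------------------------------------ #
    lo, hi = config.deep_del_prevalence_range
    prevalence = rng.uniform(lo, hi, size=config.n_patients)
    noise = rng.lognormal(0.0, config.volume_noise_sd, size=config.n_patients)
    volume = (
        config.volume_max_cc
        * (1.0 - prevalence) ** config.volume_exponent
        * noise
    )
    order = np.argsort(volume, kind="stable")
    best = [patients[i] for i in order[: config.n_best_responders]]
    truth.best_responders = best

    planted_idx = gene_model.index[
        gene_model["gene_id"] == config.planted_gene_id
    ][0]

    sample_rows = []
    variant_frames = []
    segment_frames = []
    fish_rows = []
    junction_rows = []

    # expression setup (shared across samples)
    gene_ids = list(gene_model["gene_id"])
    base_mean = rng.lognormal(np.log(100.0), 1.0, size=config.n_genes)
    base_mean[planted_idx] = 300.0
    de_pool = [i for i in range(config.n_genes) if i != planted_idx]
    de_idx = rng.choice(de_pool, size=min(config.n_de_genes, len(de_pool)),
                        replace=False)
    de_sign = np.where(np.arange(len(de_idx)) % 2 == 0, 1.0, -1.0)
    true_lfc = np.zeros(config.n_genes)
    true_lfc[planted_idx] = config.de_logfc
    true_lfc[de_idx] = de_sign * config.de_logfc
    truth.de_status = dict(zip(gene_ids, true_lfc))
    count_cols: dict[str, np.ndarray] = {}

    for pi, patient in enumerate(patients):
        vol = float(volume[pi])
        prev = float(prevalence[pi])
        is_best = patient in best
        purity_bx = float(rng.uniform(*config.purity_range))
        purity_tx = float(rng.uniform(*config.purity_range))
        unclear = bool(rng.random() < config.frac_unclear_purity)

        # clinical derivations
        any_tumor = vol > 0.02
        gleason = 6 if vol <= 1.0 else 8
        involution = vol < 0.6 * config.volume_max_cc
        response = classify_response(vol, gleason, any_tumor, involution)
        truth.residual_volume_cc[patient] = vol

        # -------------------- clonal structure -------------------- #
        k_lo, k_hi = config.clones_per_tumor
        n_clones = int(rng.integers(k_lo, k_hi + 1))
        ccf_pre = np.concatenate([[1.0], rng.uniform(0.2, 0.8, n_clones - 1)])
        ccf_post = np.clip(ccf_pre + rng.normal(0, 0.02, n_clones), 0.0, 1.0)
        ccf_post[0] = 1.0
        truth.clone_ccfs_pre[patient] = ccf_pre
        truth.clone_ccfs_post[patient] = ccf_post

        # -------------------- copy-number losses -------------------- #
        # background losses on distinct genes (never the planted gene)
        n_bg = int(rng.poisson(4))
        bg_pool = [i for i in range(config.n_genes) if i != planted_idx]
        bg_genes = rng.choice(bg_pool, size=min(n_bg, len(bg_pool)),
                              replace=False)
        losses_pre = []  # (gene_idx, major, minor, fraction)
        losses_tx = []
        for g in bg_genes:
            major, minor = (1, 0) if rng.random() < 0.7 else (0, 0)
            frac = float(rng.uniform(0.15, 0.95))
            losses_pre.append((int(g), major, minor, frac))
            if rng.random() < 0.7:  # loss persists after treatment
                losses_tx.append(
                    (int(g), major, minor,
                     float(np.clip(frac + rng.normal(0, 0.03), 0.12, 1.0)))
                )
        # post-treatment-only losses
        n_new = int(rng.poisson(2))
        new_genes = rng.choice(bg_pool, size=min(n_new, len(bg_pool)),
                               replace=False)
        for g in new_genes:
            losses_tx.append((int(g), 1, 0, float(rng.uniform(0.15, 0.95))))

        # planted subclonal deep deletion over the sensitivity gene:
        # present pre-treatment, depleted by treatment in the best responders
        plant_frac = float(np.clip(prev, 0.15, 0.85))
        plant_pre = is_best or prev >= 0.12
        if plant_pre:
            losses_pre.append((int(planted_idx), 0, 0, plant_frac))
        truth.planted_loss_pre[patient] = plant_pre
        keep_post = plant_pre and not is_best
        if keep_post:
            losses_tx.append(
                (int(planted_idx), 0, 0,
                 float(np.clip(plant_frac + rng.normal(0, 0.03), 0.12, 0.9)))
            )
        truth.planted_loss_post[patient] = keep_post

        def _segments_for(losses, sample_id):
            rows = []
            by_chrom: dict[str, list] = {c: [] for c in clens}
            for g, major, minor, frac in losses:
                grow = gene_model.iloc[g]
                s = max(0, int(grow["start"]) - _LOSS_PAD)
                e = int(grow["end"]) + _LOSS_PAD
                by_chrom[grow["chrom"]].append((s, e, major, minor, frac))
            for chrom, length in clens.items():
                cursor = 0
                for s, e, major, minor, frac in sorted(by_chrom[chrom]):
                    if s > cursor:
                        rows.append((sample_id, chrom, cursor, s, 1, 1, 1.0))
                    rows.append((sample_id, chrom, s, e, major, minor, frac))
                    cursor = e
                if cursor < length:
                    rows.append((sample_id, chrom, cursor, length, 1, 1, 1.0))
            return rows

        s_bx_ff = f"{patient}_BX_FF"
        s_bx_ffpe = f"{patient}_BX_FFPE"
        s_tx = f"{patient}_TX"
        seg_rows = (
            _segments_for(losses_pre, s_bx_ff)
            + _segments_for(losses_pre, s_bx_ffpe)
            + _segments_for(losses_tx, s_tx)
        )
        segment_frames.append(pd.DataFrame(
            seg_rows,
            columns=["sample_id", "chrom", "start", "end", "major_cn",
                     "minor_cn", "cn_fraction"],
        ))

        # -------------------- SNVs -------------------- #
        # positions avoid every loss interval of the patient (keeps the local
        # copy state an unambiguous diploid 1+1 across all samples)
        blocked = set()
        for g, *_ in losses_pre + losses_tx:
            blocked.add(int(g))
        n_snv = config.n_snvs_per_patient
        chroms = np.empty(n_snv, dtype=object)
        poss = np.empty(n_snv, dtype=int)
        seen = set()
        i = 0
        while i < n_snv:
            c = str(int(rng.integers(1, _N_CHROMS + 1)))
            pos = int(rng.integers(1, clens[c]))
            gidx = _gene_index_at(pos, c, config.n_genes)
            if gidx is not None and gidx in blocked:
                continue
            if (c, pos) in seen:
                continue
            seen.add((c, pos))
            chroms[i], poss[i] = c, pos
            i += 1
        ref_i = rng.integers(0, 4, size=n_snv)
        alt_shift = rng.integers(1, 4, size=n_snv)
        refs = _BASES[ref_i]
        alts = _BASES[(ref_i + alt_shift) % 4]
        clone_of = rng.choice(
            n_clones, size=n_snv,
            p=np.r_[0.5, np.full(n_clones - 1, 0.5 / (n_clones - 1))]
            if n_clones > 1 else [1.0],
        )
        # low-frequency subclonal tail: CCF drawn per variant, shared across
        # timepoints, replacing the clone assignment for a fraction of SNVs
        in_tail = rng.random(n_snv) < config.snv_tail_fraction
        tail_ccf = rng.uniform(0.02, 0.3, size=n_snv)

        def _variant_frame(sample_id, purity, ccfs):
            snv_ccf = np.where(in_tail, tail_ccf, ccfs[clone_of])
            ref_ct, alt_ct = _draw_reads(
                rng, snv_ccf, purity, config.mean_depth
            )
            return pd.DataFrame({
                "sample_id": sample_id, "chrom": chroms, "pos": poss,
                "ref": refs, "alt": alts,
                "ref_count": ref_ct, "alt_count": alt_ct,
            })

        vf_ff = _variant_frame(s_bx_ff, purity_bx, ccf_pre)
        vf_ffpe = _variant_frame(s_bx_ffpe, purity_bx, ccf_pre)
        vf_tx = _variant_frame(s_tx, purity_tx, ccf_post)

        # FFPE deamination artifacts: new low-VAF C>T / G>A calls
        n_art = int(rng.poisson(config.ffpe_artifact_rate * n_snv))
        if n_art > 0:
            a_chrom = [str(int(c)) for c in rng.integers(1, _N_CHROMS + 1, n_art)]
            a_pos = [int(rng.integers(1, clens[c])) for c in a_chrom]
            is_ct = rng.random(n_art) < 0.5
            a_ref = np.where(is_ct, "C", "G")
            a_alt = np.where(is_ct, "T", "A")
            vaf = rng.uniform(*config.ffpe_vaf_range, size=n_art)
            depth = np.maximum(rng.poisson(config.mean_depth, n_art), 1)
            alt_ct = np.maximum(rng.binomial(depth, vaf), 1)
            vf_art = pd.DataFrame({
                "sample_id": s_bx_ffpe, "chrom": a_chrom, "pos": a_pos,
                "ref": a_ref, "alt": a_alt,
                "ref_count": depth - alt_ct, "alt_count": alt_ct,
            })
            vf_ffpe = pd.concat([vf_ffpe, vf_art], ignore_index=True)

        variant_frames += [vf_ff, vf_ffpe, vf_tx]

        # -------------------- sample sheet -------------------- #
        for sid, tp, pres, pur in (
            (s_bx_ff, "BX", "FF", purity_bx),
            (s_bx_ffpe, "BX", "FFPE", purity_bx),
            (s_tx, "TX", "FF", purity_tx),
        ):
            sample_rows.append({
                "patient": patient, "sample": sid, "timepoint": tp,
                "preservation": pres, "purity": round(pur, 4), "ploidy": 2.0,
                "purity_clear": not unclear,
                "residual_volume_cc": round(vol, 4), "response": response,
            })

        # -------------------- FISH -------------------- #
        prev_post = prev * 0.05 if is_best else float(
            np.clip(prev * rng.uniform(0.8, 1.1), 0.0, 1.0)
        )
        truth.deep_del_prevalence[s_bx_ffpe] = prev
        truth.deep_del_prevalence[s_tx] = prev_post
        for sid, p_dd in ((s_bx_ffpe, prev), (s_tx, prev_post)):
            n_cells = config.fish_cells_per_sample
            qc_fail = rng.random(n_cells) < 0.02
            u = rng.random(n_cells)
            target = np.where(
                u < p_dd, 0,
                np.where(u < p_dd + 0.15, 1, 2 + (rng.random(n_cells) < 0.1)),
            )
            cent = np.where(qc_fail, 0, 2 - (rng.random(n_cells) < 0.1))
            target = np.where(qc_fail, rng.integers(0, 3, n_cells), target)
            for ci in range(n_cells):
                fish_rows.append((sid, f"{sid}_c{ci:04d}",
                                  int(target[ci]), int(cent[ci])))

        # -------------------- expression & junctions -------------------- #
        for sid, treated in ((s_bx_ff, False), (s_tx, True)):
            depth_factor = rng.lognormal(0.0, 0.15)
            mu = base_mean * depth_factor
            if treated:
                mu = mu * 2.0 ** true_lfc
            r = 1.0 / config.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
            count_cols[sid] = counts
            canonical = int(rng.poisson(300 * depth_factor))
            variant_j = int(rng.poisson(1.5))
            junction_rows.append(("AR_FL_e3e4", sid, canonical))
            junction_rows.append(("AR_V7_e3cE3", sid, variant_j))

    samples = pd.DataFrame(sample_rows)
    variants = pd.concat(variant_frames, ignore_index=True)
    segments = pd.concat(segment_frames, ignore_index=True)
    counts = pd.DataFrame(count_cols,
                          index=pd.Index(gene_ids, name="gene_id"))
    junctions = pd.DataFrame(junction_rows,
                             columns=["junction_id", "sample", "reads"])
    fish = pd.DataFrame(
        fish_rows,
        columns=["sample", "cell_id", "target_signals", "centromere_signals"],
    )
    cohort = Cohort(config, samples, variants, segments, gene_model, counts,
                    junctions, fish, truth)
    if out_dir is not None:
        cohort.paths = cohort.write(out_dir)
    return cohort


def _gene_index_at(pos: int, chrom: str, n_genes: int) -> int | None:
    """Index of the gene block (gene +/- loss padding) containing pos."""
    per_chrom = -(-n_genes // _N_CHROMS) if n_genes else 0
    offset = pos - (50_000 - _LOSS_PAD)
    if offset < 0:
        return None
    j = offset // _GENE_SPACING
    within = offset % _GENE_SPACING
    if within >= _GENE_LENGTH + 2 * _LOSS_PAD:
        return None
    idx = (int(chrom) - 1) * per_chrom + int(j)
    return idx if idx < n_genes else None
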