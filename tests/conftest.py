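import warnings

import pytest

from neoclone.cohort_sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A reduced cohort for fast file-level tests (6 patients)."""
    return SimConfig(
        n_patients=6,
        n_snvs_per_patient=40,
        n_genes=60,
        planted_gene_id="G0030",
        fish_cells_per_sample=120,
        n_best_responders=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_cohort_dir(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        simulate_cohort(small_config, out_dir=out)
    return out


def ffpe_pairs(cohort):
    """Split a cohort's pre-treatment variants into FF / FFPE dicts."""
    meta = cohort.samples.set_index("sample")
    ff, ffpe = {}, {}
    for sid, sub in cohort.variants.groupby("sample_id"):
        m = meta.loc[sid]
        if m["timepoint"] != "BX":
            continue
        target = ff if m["preservation"] == "FF" else ffpe
        target[str(m["patient"])] = sub
    return ff, ffpe
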