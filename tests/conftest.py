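import numpy as np
import pandas as pd
import pytest

import prs_transfer as pt


@pytest.fixture(scope="session")
def tiny_config():
    """A small but non-trivial study: fast enough for every unit test."""
    return pt.SimulationConfig(
        n_snps=40, n_low_info=4, n_cases=800, n_controls=800,
        n_prospective=1000, n_strata=3, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_config):
    return pt.gen_weight_panel(tiny_config)


@pytest.fixture(scope="session")
def tiny_study(tiny_panel, tiny_config):
    """(cohort-with-standardised-PRS, dosages, ground truth)."""
    cohort, dosages, gt = pt.gen_case_control_cohort(tiny_panel, tiny_config)
    cohort = cohort.copy()
    cohort["prs_std"] = cohort["prs_raw"] / tiny_config.control_sd_pop1
    return cohort, dosages, gt


@pytest.fixture(scope="session")
def strong_fh_cohort():
    """Cohort with a strong PRS effect so family-history signals are clear."""
    cfg = pt.SimulationConfig(
        n_snps=60, n_low_info=0, per_sd_log_or=np.log(3.0),
        n_cases=4000, n_controls=4000, n_strata=3, seed=21,
    )
    panel = pt.gen_weight_panel(cfg)
    cohort, _, gt = pt.gen_case_control_cohort(panel, cfg)
    cohort = pt.gen_family_history(cohort, cfg, gt)
    cohort["prs_std"] = cohort["prs_raw"] / cfg.control_sd_pop1
    return cohort, cfg, gt


def toy_weight_frame(n=3, **overrides):
    """Hand-buildable weight table for unit tests."""
    base = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "chrom": [1] * n,
        "pos": np.arange(1, n + 1) * 100,
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "weight_overall": np.linspace(0.1, 0.3, n),
        "weight_erpos": np.linspace(0.1, 0.3, n),
        "weight_erneg": np.linspace(0.05, 0.15, n),
        "info": [1.0] * n,
        "freq_pop1": [0.3] * n,
        "freq_pop2": [0.2] * n,
    })
    for k, v in overrides.items():
        base[k] = v
    return base
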