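"""Shared fixtures: small synthetic cohorts and one mid-size pipeline run,
generated once per session."""

import numpy as np
import pytest

from childses import cohort as coh
from childses.pipeline import PipelineConfig, run_pipeline


def clean_spec(n: int, seed: int, **overrides) -> coh.CohortSpec:
    """A fully observed cohort: no module subsampling, no nonresponse, no
    education dichotomization or missingness."""
    parent_edu = coh._default_parent_edu()
    parent_edu.update({"dichotomized_fraction": 0.0, "p_missing_base": 0.0,
                       "p_missing_not_lived": 0.0})
    base = dict(n_respondents=n, seed=seed, module_fractions={},
                core_missing_rate={}, parent_edu=parent_edu,
                vulnerability_base_rate=0.0)
    base.update(overrides)
    return coh.CohortSpec(**base)


@pytest.fixture(scope="session")
def clean_cohort():
    """n = 5,000 fully observed cohort (the parameter-recovery workhorse)."""
    spec = clean_spec(5000, seed=20170913)
    return spec, coh.generate_cohort(spec)


@pytest.fixture(scope="session")
def masked_cohort():
    """Default observation process at n = 12,000."""
    spec = coh.CohortSpec(n_respondents=12000, seed=20170914)
    table = coh.apply_missingness(coh.generate_cohort(spec), spec)
    return spec, table


@pytest.fixture(scope="session")
def nomiss_run(tmp_path_factory):
    """Pipeline run on a fully observed cohort (no-exclusion limit)."""
    cfg = PipelineConfig(n_respondents=2500, seed=11, run_delta_r2=False,
                         output_dir=str(tmp_path_factory.mktemp("nomiss")))
    cfg.spec_overrides = {
        "module_fractions": {}, "core_missing_rate": {},
        "parent_edu": {"dichotomized_fraction": 0.0, "p_missing_base": 0.0,
                       "p_missing_not_lived": 0.0},
        "vulnerability_base_rate": 0.0,
    }
    out = run_pipeline(cfg)
    return cfg, out


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Pipeline run with the full default observation process, n = 10,000."""
    cfg = PipelineConfig(n_respondents=10000, seed=20170915,
                         run_delta_r2=False,
                         output_dir=str(tmp_path_factory.mktemp("default_run")))
    out = run_pipeline(cfg)
    return cfg, out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
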