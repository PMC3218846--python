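import numpy as np
import pytest

from cpgrates.alignments import filter_introns
from cpgrates.features import build_features
from cpgrates.pipeline import compute_rates
from cpgrates.simulate import SimulationConfig, simulate_study
from cpgrates.stats import COVARIATES, complete_cases


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-intron synthetic study under the default conditions."""
    return simulate_study(SimulationConfig(n_introns=40, seed=123))


@pytest.fixture(scope="session")
def study2000():
    """A 2,000-intron study with the full estimation pipeline applied.

    Shared by the event-log exactness checks and the correlation
    invariants; returns (bundle, rates table, joined analysis table).
    """
    bundle = simulate_study(SimulationConfig(n_introns=2000, seed=1009))
    kept, _ = filter_introns(bundle.alignments)
    rates_df, _ = compute_rates(kept, fit_exchangeabilities=False)
    feats = build_features(
        kept,
        bundle.methylation_track,
        bundle.recombination_track,
        bundle.cgi_track,
        bundle.dhs_track,
        bundle.expression,
    )
    joined = rates_df.merge(feats, on="intron_id")
    joined = joined[joined["dataset"] != "discard"]
    analysis = complete_cases(joined, list(COVARIATES))
    return bundle, rates_df, analysis
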