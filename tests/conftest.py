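import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# narrowband/zero-channel warnings are exercised deliberately in fixtures
warnings.filterwarnings("ignore", message="all-zero", category=RuntimeWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_recovery_templates(n_subjects=10, duration=60.0, strength=0.75,
                            jitter_sd=0.6, noise_sd=1.0):
    """Three-group templates whose ONLY group differences are 12 beta-band
    edges: six planted in GAD, six different ones in DD, none in HC."""
    from plistack.synthetic import CohortTemplate, CouplingEdge

    gad_pairs = [("Fp1", "F3"), ("Fp2", "F4"), ("F3", "F4"),
                 ("F7", "C3"), ("F8", "C4"), ("Fp1", "F8")]
    dd_pairs = [("Fp1", "Fp2"), ("F7", "F8"), ("F3", "C3"),
                ("F4", "C4"), ("T3", "F7"), ("T4", "F8")]

    def edges(pairs):
        return tuple(
            CouplingEdge(a, b, "beta", lag=1.2, strength=strength,
                         jitter_sd=jitter_sd)
            for a, b in pairs
        )

    mk = lambda g, e: CohortTemplate(group=g, edges=e, n_subjects=n_subjects,
                                     noise_sd=noise_sd, duration=duration)
    return (mk("HC", ()), mk("GAD", edges(gad_pairs)), mk("DD", edges(dd_pairs)))


def planted_feature_ids():
    """Feature ids of the 12 group-discriminative beta edges above."""
    from plistack.connectivity import feature_names

    names = feature_names()
    pairs = [("Fp1", "F3"), ("Fp2", "F4"), ("F3", "F4"), ("F7", "C3"),
             ("F8", "C4"), ("Fp1", "F8"), ("Fp1", "Fp2"), ("F7", "F8"),
             ("F3", "C3"), ("F4", "C4"), ("T3", "F7"), ("T4", "F8")]
    from plistack.montage import DEFAULT_MONTAGE

    order = {ch: i for i, ch in enumerate(DEFAULT_MONTAGE)}
    ids = []
    for a, b in pairs:
        a, b = (a, b) if order[a] < order[b] else (b, a)
        ids.append(names.index(f"beta__{a}__{b}"))
    return sorted(ids)


def tiny_config(out_dir, seed=1):
    """Desk-scale end-to-end configuration (about a minute of compute)."""
    from plistack.pipeline import RunConfig

    return RunConfig(
        out_dir=str(out_dir), n_subjects=(3, 3, 3), duration=60.0,
        noise_sd=1.0, jitter_sd=0.6, window_lengths=(2, 4), analysis_window=4,
        p_rank=2, k_rank=3, p_eval=1, k_eval=3, candidate_sizes=(10, 30),
        n_trials=3, n_estimators=40, n_oof_folds=3, seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One completed tiny pipeline run shared across tests."""
    from plistack.pipeline import run

    cfg = tiny_config(tmp_path_factory.mktemp("run") / "a")
    return cfg, run(cfg)


@pytest.fixture(scope="session")
def recovery_features():
    """PLI feature table for the 12-planted-edge cohort (seed 11)."""
    from plistack.experiments import cohort_features
    from plistack.synthetic import generate_cohort

    recs = generate_cohort(make_recovery_templates(n_subjects=8), seed=11)
    return cohort_features(recs, window_length=4)
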