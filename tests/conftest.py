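import pytest

from ethoseq import synthetic_data as sd
from ethoseq.event_log import BehaviorEvent, Bout
from ethoseq.repeatability import MCMCSettings, compute_icc, fit_poisson_glmm


def bouts_from_states(state_lists, trial_id="T1", actor="A", snap=5.0):
    """Build Bout objects from raw state sequences (events on a 5-s grid)."""
    bouts = []
    for states in state_lists:
        evs = tuple(
            BehaviorEvent(trial_id, actor, s, snap * i,
                          snap if s != "end" else 0.0)
            for i, s in enumerate(states))
        bouts.append(Bout(trial_id, evs, terminated=states[-1] == "end"))
    return bouts


def simulate_bouts(config, n, rng):
    """n bouts drawn from a SimConfig's planted chain, as Bout objects."""
    return bouts_from_states(
        [sd.simulate_bout_states(config, rng) for _ in range(n)])


@pytest.fixture(scope="session")
def null_fixture_dir(tmp_path_factory):
    """A complete synthetic dataset from the null_female preset, on disk."""
    out = tmp_path_factory.mktemp("null_fixture")
    sd.make_fixture(sd.null_female_config(seed=5), out)
    return out


def _fit_icc_panels(v_female, v_resid, seeds):
    results = []
    for k in seeds:
        panel, truth = sd.simulate_count_panel(
            n_females=200, n_rounds=3, mu=1.5, V_female=v_female,
            V_trial=0.0, V_resid=v_resid, seed=k)
        post = fit_poisson_glmm(panel, MCMCSettings(seed=k))
        results.append((compute_icc(post), truth))
    return results


@pytest.fixture(scope="session")
def icc_signal_fits():
    """20 seeded fits on panels with true latent ICC 0.8 (200 females x 3)."""
    return _fit_icc_panels(0.8, 0.2, range(20))


@pytest.fixture(scope="session")
def icc_null_fits():
    """20 seeded fits on panels with zero among-female variance."""
    return _fit_icc_panels(0.0, 0.2, range(100, 120))
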