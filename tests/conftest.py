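import numpy as np
import pytest

from trajmix.io_data import CountsDataset, PerturbationSchedule
from trajmix.mixture import ModelState, PosteriorSamples
from trajmix.signatures import Hyperparams, PrototypeSignature


@pytest.fixture(scope="session")
def toy_schedule() -> PerturbationSchedule:
    """Short five-interval study: pulses on days [10,12) and [30,32)."""
    return PerturbationSchedule(
        boundaries=((0, 10), (10, 12), (12, 30), (30, 32), (32, 50))
    )


@pytest.fixture(scope="session")
def toy_times() -> np.ndarray:
    """16 irregular observation days covering all five intervals."""
    return np.array([0, 3, 6, 9, 10, 11, 12, 13, 15, 18, 22, 27, 30, 32, 36, 45.0])


def make_dataset(counts, times, subject="S1", totals=None, taxonomy=None):
    counts = np.asarray(counts)
    return CountsDataset(
        subjects=[subject],
        counts={subject: counts},
        times={subject: np.asarray(times, float)},
        refotus={subject: [f"otu{i+1}" for i in range(counts.shape[0])]},
        taxonomy=taxonomy or {},
        totals={subject: totals} if totals is not None else {},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_samples(z_draws, subjects_of_units, signatures_per_draw=None, gamma=None):
    """Hand-build a PosteriorSamples object from assignment lists.

    ``z_draws``: list of per-draw assignment vectors; ``subjects_of_units``:
    subject label per unit.  Signatures default to all-tied prototypes.
    """
    n_units = len(subjects_of_units)
    units = []
    counter: dict[str, int] = {}
    for s in subjects_of_units:
        counter[s] = counter.get(s, 0) + 1
        units.append((s, f"otu{counter[s]}"))
    draws = []
    for j, z in enumerate(z_draws):
        z = np.asarray(z, int)
        k = int(z.max()) + 1
        sigs = (
            signatures_per_draw[j]
            if signatures_per_draw is not None
            else [PrototypeSignature(mu_a=float(i)) for i in range(k)]
        )
        draws.append(
            ModelState(
                signatures=sigs,
                z=z,
                gamma=np.zeros(n_units) if gamma is None else np.asarray(gamma, float),
                eps1=0.3,
                eps2=0.6,
                alpha=1.0,
                iteration=j,
            )
        )
    subjects = list(dict.fromkeys(subjects_of_units))
    return PosteriorSamples(units=units, subjects=subjects, draws=draws)


@pytest.fixture(scope="session")
def default_hyper() -> Hyperparams:
    return Hyperparams(mu_a_mean=5.0)
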