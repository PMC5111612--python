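import numpy as np
import pytest

from perrcox import PairedSurvivalData


def counts_dataset(mp_exposed, ms_exposed, mp_unexposed, ms_unexposed):
    """Saturated binary-treatment dataset from informative pair counts.

    ``mp`` pairs have the prior event first (d_prior=1, t_prior < t_study);
    ``ms`` pairs have the study event first.  The joint pairwise MLE is then
    closed-form: exp(theta+alpha) = ms_E/mp_E, exp(alpha) = ms_U/mp_U.
    """
    rows = []
    for x, mp, ms in ((1.0, mp_exposed, ms_exposed), (0.0, mp_unexposed, ms_unexposed)):
        for _ in range(mp):
            rows.append((1.0, 1.0, 2.0, 0.0, x))
        for _ in range(ms):
            rows.append((2.0, 0.0, 1.0, 1.0, x))
    a = np.array(rows)
    return PairedSurvivalData(subject_id=np.arange(len(rows)),
                              t_prior=a[:, 0], d_prior=a[:, 1],
                              t_study=a[:, 2], d_study=a[:, 3], x=a[:, 4:5])


def random_paired(rng, n=60, q=1, p_event=0.7):
    """Generic random paired dataset (no structure, for algebraic checks)."""
    return PairedSurvivalData(
        subject_id=np.arange(n),
        t_prior=rng.exponential(size=n),
        d_prior=(rng.random(n) < p_event).astype(float),
        t_study=rng.exponential(size=n),
        d_study=(rng.random(n) < p_event).astype(float),
        x=rng.normal(size=(n, q)))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
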