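import numpy as np
import pytest

from spikemotifs.data_model import Role, Session, SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_train(times, duration=10.0, role=Role.IN, unit_id="u", **kw):
    return SpikeTrain(
        times=np.asarray(times, dtype=float),
        duration=duration,
        role=role,
        unit_id=unit_id,
        **kw,
    )


def poisson_train(rate, duration, rng, role=Role.IN, unit_id="u"):
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0, duration, n))
    t = t[np.concatenate([[True], np.diff(t) >= 0.6e-3])]
    return make_train(t, duration, role, unit_id)


@pytest.fixture
def small_session(rng):
    in_tr = poisson_train(8.0, 60.0, rng, Role.IN, "in")
    pc = poisson_train(26.0, 60.0, rng, Role.PC_SIMPLE, "pc_simple")
    cs = poisson_train(1.2, 60.0, rng, Role.PC_COMPLEX, "pc_complex")
    return Session(trains={"in": in_tr, "pc_simple": pc, "pc_complex": cs})
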