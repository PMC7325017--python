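import numpy as np
import pytest

from massetry import PhantomParams, TimepointData, apply_transform, kabsch, make_phantom
from massetry.transforms import RigidTransform


def random_rigid(rng, max_deg=180.0, max_trans=50.0) -> RigidTransform:
    axis = rng.standard_normal(3)
    return RigidTransform.from_axis_angle(
        axis,
        float(rng.uniform(-max_deg, max_deg)),
        rng.uniform(-max_trans, max_trans, 3),
    )


def register_case(case):
    """Kabsch on the phantom's stable skull landmarks; aligned post state."""
    names = sorted(n for n in case.pre.landmarks.points if n.startswith("skull"))
    T = kabsch(
        [case.post.landmarks[n] for n in names],
        [case.pre.landmarks[n] for n in names],
    )
    return T, TimepointData(
        face=apply_transform(case.post.face, T),
        masseters={s: apply_transform(m, T) for s, m in case.post.masseters.items()},
        landmarks=case.post.landmarks.transformed(T.apply),
    )


@pytest.fixture(scope="session")
def coarse_params():
    # 5 mm target edge keeps the property tests fast; recovery accuracy at
    # this resolution is still well below the tolerances asserted
    return PhantomParams(resolution_mm=5.0)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_params):
    return make_phantom(coarse_params)


@pytest.fixture(scope="session")
def coarse_frame(coarse_phantom):
    from massetry import build_frame

    return build_frame(coarse_phantom.pre.landmarks)


@pytest.fixture(scope="session")
def fine_phantom():
    # default 2 mm edge target; used where discretization bias matters
    return make_phantom(PhantomParams())
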