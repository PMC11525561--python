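import numpy as np
import pytest

import lcatpam as lp


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def two_residue_frames():
    """10 frames of two CA atoms (CYS 50 at origin, ASN 65 on x) with known
    distances 20.0, 20.1, ... Å."""
    roster = [
        lp.AtomKey("A", 50, "CA", "CYS"),
        lp.AtomKey("A", 65, "CA", "ASN"),
    ]
    n = 10
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = 20.0 + 0.1 * np.arange(n)
    return lp.TrajectoryFrames(
        roster=roster, coords=coords, times=np.arange(n, dtype=float),
        source_label="fixture",
    )


@pytest.fixture
def random_frames(rng):
    """100 frames of two CA atoms at random (well separated) positions."""
    roster = [
        lp.AtomKey("A", 50, "CA", "CYS"),
        lp.AtomKey("A", 65, "CA", "ASN"),
    ]
    coords = rng.uniform(-30, 30, size=(100, 2, 3))
    coords[:, 1, :] += 80.0  # keep the pair separated so distances stay > 0
    return lp.TrajectoryFrames(
        roster=roster, coords=coords, times=np.arange(100, dtype=float),
        source_label="random",
    )


def rigid_transform(coords, rng):
    """Apply one random rotation + translation to every frame."""
    # QR of a random matrix gives a uniform-ish orthogonal matrix
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    t = rng.uniform(-50, 50, size=3)
    return coords @ q.T + t
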