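import numpy as np
import pytest

from phagosim.analysis import (classify_shape, extract_barriers,
                               success_rate)
from phagosim.mesh import TriMesh, build_icosphere


def test_classify_sphere(icosphere3):
    assert classify_shape(icosphere3).label == "sphere"


def test_classify_tube():
    from phagosim.initial_conditions import prolate_mesh

    assert classify_shape(prolate_mesh(3.0)).label == "tube"


def test_classify_disk():
    from phagosim.initial_conditions import oblate_mesh

    lab = classify_shape(oblate_mesh(0.35))
    assert lab.label == "disk"


def test_classify_cup():
    from phagosim.initial_conditions import stomatocyte_mesh

    lab = classify_shape(stomatocyte_mesh())
    assert lab.label == "cup"
    assert lab.pocket_depth > 0.5


def test_classify_bowl():
    from phagosim.initial_conditions import stomatocyte_mesh

    lab = classify_shape(stomatocyte_mesh(mouth_angle=0.9,
                                          dimple_radius=0.75))
    assert lab.label == "bowl"
    assert 0.2 < lab.pocket_depth <= 0.5


def test_classify_rigid_motion_and_scale_invariant():
    from phagosim.initial_conditions import stomatocyte_mesh

    m = stomatocyte_mesh()
    rng = np.random.default_rng(3)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    moved = TriMesh(m.vertices @ q.T * 4.2 + np.array([10.0, -3.0, 7.0]),
                    m.triangles)
    assert classify_shape(moved).label == classify_shape(m).label


def test_extract_barriers_quartic_double_well():
    x = np.linspace(0.8, 1.5, 141)
    e = (x - 1.0) ** 2 * (x - 1.4) ** 2
    res = extract_barriers(x, e)
    # analytic maximum at 1.2: (0.2^2)*(0.2^2) = 1.6e-3
    assert res.H1 == pytest.approx(1.6e-3, rel=1e-3)
    assert res.H2 is None
    assert not res.barrier_absent


def test_extract_barriers_monotone():
    x = np.linspace(0.8, 1.5, 20)
    res = extract_barriers(x, 2.0 * x)
    assert res.H1 is None and res.H2 is None
    assert res.barrier_absent


def test_extract_barriers_two_wells():
    # synthetic branch with tube (1.44), disk (1.04) and cup (0.7) minima
    x = np.linspace(0.6, 1.6, 201)

    def well(x0, depth, w):
        return -depth * np.exp(-((x - x0) / w) ** 2)

    e = 2.2 + well(1.44, 0.15, 0.05) + well(1.04, 0.4, 0.1) + \
        well(0.70, 0.9, 0.1)
    res = extract_barriers(x, e)
    assert len(res.minima) >= 3 and len(res.maxima) >= 2
    assert res.H1 is not None and res.H2 is not None
    assert res.H1 > 0 and res.H2 > 0


def test_success_rate_thresholds():
    frac, verdict = success_rate(["cup"] * 35)
    assert frac == 1.0 and verdict == "successful"
    frac, verdict = success_rate(["cup"] * 26 + ["tube"] * 9)
    assert frac == pytest.approx(26 / 35) and verdict == "not successful"
    frac, verdict = success_rate(["cup"] * 27 + ["tube"] * 8)
    assert frac == pytest.approx(27 / 35) and verdict == "successful"
    with pytest.raises(ValueError):
        success_rate([])
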