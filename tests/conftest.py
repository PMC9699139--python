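"""Shared phantom fixtures.

Phantoms are generated once per session: a fine (0.1 mm) clean phantom for
geometry-accuracy tests, the default 0.2 mm phantom plus its implanted
variant for pipeline tests, and a mirrored left-ear twin.
"""

import numpy as np
import pytest

from cochleapy import pose
from cochleapy.phantom import (PhantomSpec, generate_phantom, implant_phantom)


@pytest.fixture(scope="session")
def fine_phantom():
    spec = PhantomSpec(voxel_spacing=(0.1, 0.1, 0.1))
    labels, image, truth = generate_phantom(spec)
    return spec, labels, image, truth


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()  # 0.2 mm isotropic, noiseless
    labels, image, truth = generate_phantom(spec)
    return spec, labels, image, truth


@pytest.fixture(scope="session")
def implanted_phantom(default_phantom):
    spec, labels, image, truth = default_phantom
    post_image, post_truth = implant_phantom(image, spec, truth)
    return spec, labels, post_image, post_truth


@pytest.fixture(scope="session")
def left_phantom():
    spec = PhantomSpec(laterality="left")
    labels, image, truth = generate_phantom(spec)
    return spec, labels, image, truth


@pytest.fixture(scope="session")
def fine_frame(fine_phantom):
    return pose.estimate_canonical_frame(fine_phantom[3].landmarks)


@pytest.fixture(scope="session")
def default_frame(default_phantom):
    return pose.estimate_canonical_frame(default_phantom[3].landmarks)


@pytest.fixture(scope="session")
def fine_centerline(fine_phantom, fine_frame):
    from cochleapy import scala_geometry
    labels = fine_phantom[1]
    return scala_geometry.extract_centerline(labels, fine_frame,
                                             structure="labyrinth")


@pytest.fixture(scope="session")
def fine_sections(fine_phantom, fine_frame, fine_centerline):
    from cochleapy import scala_geometry
    return scala_geometry.extract_cross_sections(fine_phantom[1], fine_frame,
                                                 fine_centerline)


@pytest.fixture(scope="session")
def fine_paths(fine_sections, fine_frame):
    from cochleapy import scala_geometry
    return scala_geometry.landmark_paths(fine_sections, fine_frame)


@pytest.fixture()
def simple_frame():
    """Axis-aligned canonical frame around the origin."""
    lm = pose.LandmarkSet(C=np.array([0.0, 0.0, 0.0]),
                          RW=np.array([3.0, 0.0, 0.0]),
                          Ap=np.array([0.0, 0.0, 5.0]), laterality="right")
    return pose.estimate_canonical_frame(lm)
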