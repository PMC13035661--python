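"""Shared fixtures: phantoms are generated once per session and reused."""

import numpy as np
import pytest
from hypothesis import settings

import aortamorph as am
from aortamorph.cli import RunConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


class MeasuredPhantom:
    """A voxel phantom together with every pipeline product, computed once."""

    def __init__(self, spec: am.PhantomSpec, plane_res: float | None = None):
        self.spec = spec
        self.vol, self.truth = am.voxelize_phantom(spec)
        self.cl = am.extract_centerline(self.vol, step=1.0)
        self.profile = am.diameter_profile(
            self.vol,
            self.cl,
            end_guard=10.0,
            plane_res=plane_res if plane_res is not None else spec.spacing,
        )
        self.measures = am.global_measures(self.vol, self.cl, self.profile)
        self.per_sample = am.false_lumen_per_sample(self.vol, self.cl)

    def fl_loc(self, section_length=30.0):
        return am.fl_loc(
            self.vol,
            self.cl,
            self.profile,
            section_length,
            per_sample=self.per_sample,
        )


@pytest.fixture(scope="session")
def tube_1mm():
    """Uniform half-CFL tube, 100 mm x r 15 mm, 1 mm voxels."""
    return MeasuredPhantom(am.PhantomSpec(spacing=1.0))


@pytest.fixture(scope="session")
def bulge_1mm():
    """Tube with a Gaussian bulge (A=5 mm at s=50, w=10 mm), 1 mm voxels."""
    return MeasuredPhantom(am.PhantomSpec(spacing=1.0, bulge=(5.0, 50.0, 10.0)))


@pytest.fixture(scope="session")
def tube_05mm():
    """The reference-resolution uniform tube (0.5 mm voxels)."""
    return MeasuredPhantom(am.PhantomSpec(spacing=0.5))


@pytest.fixture(scope="session")
def bulge_05mm():
    """The reference-resolution bulge phantom (0.5 mm voxels)."""
    return MeasuredPhantom(am.PhantomSpec(spacing=0.5, bulge=(5.0, 50.0, 10.0)))


@pytest.fixture(scope="session")
def tilted_tube_1mm():
    """Straight tube tilted 30 degrees to the grid axes, 1 mm voxels."""
    direction = (np.sin(np.pi / 6), 0.0, np.cos(np.pi / 6))
    return MeasuredPhantom(am.PhantomSpec(spacing=1.0, direction=direction))


@pytest.fixture(scope="session")
def candy_cane_1mm():
    """Arch (R=40 mm) + descending limb (80 mm), thrombus present."""
    return MeasuredPhantom(
        am.PhantomSpec(
            centerline_kind="candy_cane",
            arch_radius=40.0,
            descending_length=80.0,
            th_fraction=0.3,
            spacing=1.0,
        )
    )


@pytest.fixture()
def run_config():
    return RunConfig()
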