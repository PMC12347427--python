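import numpy as np
import pytest

from femrem.geometry import (
    FemurParams,
    StemType,
    build_femur_contour,
    build_stem_contour,
    place_stem,
)
from femrem.meshing import Mesh, Region, default_materials


@pytest.fixture(scope="session")
def default_femur():
    return build_femur_contour(FemurParams())


@pytest.fixture(scope="session")
def stems():
    return {st: build_stem_contour(st) for st in StemType}


@pytest.fixture(scope="session")
def placed_neutral(default_femur, stems):
    return {st: place_stem(default_femur, stem, 0.0) for st, stem in stems.items()}


@pytest.fixture(scope="session")
def materials():
    return default_materials()


def make_rect_mesh(length, height, nx, ny, region=Region.CORTICAL):
    """Structured right-triangle mesh of a rectangle (single material)."""
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(ny):
        for i in range(nx):
            n0 = j * (nx + 1) + i
            n1 = n0 + 1
            n2 = n0 + nx + 1
            n3 = n2 + 1
            if (i + j) % 2 == 0:  # alternate diagonals to avoid bias
                tris.append([n0, n1, n3])
                tris.append([n0, n3, n2])
            else:
                tris.append([n0, n1, n2])
                tris.append([n1, n3, n2])
    tris = np.asarray(tris)
    return Mesh(nodes=nodes, triangles=tris, region=np.array([region] * len(tris), dtype=object))


@pytest.fixture(scope="session")
def rect_mesh():
    return make_rect_mesh


@pytest.fixture(scope="session")
def default_patient_result():
    """One shared end-to-end patient run (coarse mesh) for downstream tests."""
    from dataclasses import replace

    from femrem.cohort import generate_patient
    from femrem.pipeline import SimulationSettings, run_patient

    rec = generate_patient(0, StemType.PROXIMA)
    rec = replace(
        rec, geometry_params=FemurParams(), body_weight=70.0, pauwels_angle=16.0
    )
    return run_patient(rec, SimulationSettings(max_element_area=3.0))
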