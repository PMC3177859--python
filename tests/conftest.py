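"""Shared fixtures: small sphere phantoms and their extracted surfaces.

Session-scoped so the voxelisation + surface extraction cost is paid once.
The small phantom uses newborn layer thicknesses on a 30 mm brain sphere at
0.75 mm voxels: big enough for sub-voxel surface accuracy, small enough to
keep the suite fast.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
import trimesh

from scalpmap.distances import ray_normal_distance_map
from scalpmap.phantom import (brain_mask_from_truth, default_layer_params,
                              make_layered_head, phantom_landmarks)
from scalpmap.surfaces import (SurfaceMesh, brain_hull, extract_isosurface,
                               scalp_mask, truncate_ventral, vertex_normals)

SMALL_RADIUS = 30.0
SMALL_SPACING = 0.75
SCALP_THRESHOLD = 90.0  # half the cutis intensity


@pytest.fixture(scope="session")
def newborn_params():
    return replace(default_layer_params("newborn"),
                   brain_semiaxes=(SMALL_RADIUS,) * 3)


@pytest.fixture(scope="session")
def small_phantom(newborn_params):
    """(volume, truth) for a newborn-layer sphere phantom, r=30, 0.75 mm."""
    return make_layered_head(newborn_params, spacing=SMALL_SPACING, margin=4.0)


@pytest.fixture(scope="session")
def small_surfaces(small_phantom):
    """dict with scalp mesh, brain mask, hull and landmarks of the phantom."""
    volume, truth = small_phantom
    head = scalp_mask(volume, SCALP_THRESHOLD)
    scalp = extract_isosurface(head)
    brain = brain_mask_from_truth(truth, volume)
    hull = brain_hull(brain)
    return {
        "volume": volume,
        "truth": truth,
        "head_mask": head,
        "brain_mask": brain,
        "scalp": scalp,
        "hull": hull,
        "landmarks": phantom_landmarks(truth),
    }


@pytest.fixture(scope="session")
def small_distance_map(small_surfaces):
    hull = truncate_ventral(small_surfaces["hull"], cut_fraction=0.3)
    return ray_normal_distance_map(hull, small_surfaces["scalp"])


@pytest.fixture(scope="session")
def icosphere():
    """Unit-style analytic sphere mesh (r=20 mm, 1280 faces) with normals."""
    tm = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    mesh = SurfaceMesh(vertices=np.asarray(tm.vertices, float),
                       faces=np.asarray(tm.faces, int))
    return vertex_normals(mesh)


@pytest.fixture(scope="session")
def tilted_ellipsoid():
    """Rotated ellipsoid mesh: no symmetry plane aligned with image axes."""
    tm = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    verts = np.asarray(tm.vertices, float) * np.array([30.0, 24.0, 18.0])
    angle = np.deg2rad(25.0)
    rot = trimesh.transformations.rotation_matrix(angle, [1.0, 0.7, 0.3])[:3, :3]
    mesh = SurfaceMesh(vertices=verts @ rot.T, faces=np.asarray(tm.faces, int))
    return vertex_normals(mesh)
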