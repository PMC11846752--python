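"""Shared fixtures: small synthetic domains, the confined-bar benchmark and
reusable solver configurations."""

import numpy as np
import pytest

import bonerom as br
from bonerom.geometry import SimplexMesh
from bonerom.geometry import _structured_triangles


@pytest.fixture(scope="session")
def small_spec():
    """169-node plate (12x12 cells) with a 2-cell-wide implant; small enough
    for dense oracles."""
    return br.DomainSpec(
        extents=(6.0, 6.0),
        implant_polygon=np.array([[2.5, 2.0], [3.5, 2.0], [3.5, 4.0], [2.5, 4.0]]),
        element_size=0.5,
        pose_bounds={"dx": (-1.0, 1.0), "dy": (-1.0, 1.0), "gamma": (-1.0, 1.0)},
    )


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return br.build_reference_domain(small_spec)


@pytest.fixture(scope="session")
def small_morph_op(small_mesh):
    return br.build_morph_operator(small_mesh)


def make_bar(nx=20, ny=2, length=10.0, height=1.0):
    """Confined homogeneous 2D bar: lateral displacement blocked everywhere,
    left end held axially.  Returns the mesh plus helper node/facet sets."""
    nodes, tris = _structured_triangles((length, height), [nx, ny])
    n = len(nodes)
    mesh = SimplexMesh(
        nodes=nodes,
        elements=tris,
        node_sets={
            "fixed_boundary": np.arange(n),
            "implant": np.array([], dtype=np.int64),
            "interior": np.array([], dtype=np.int64),
        },
        element_material=np.full(len(tris), "bone", dtype="U7"),
    )
    left = np.flatnonzero(nodes[:, 0] < 1e-9)
    right_facets = mesh.boundary_facets()
    right_facets = right_facets[
        np.all(nodes[right_facets][:, :, 0] > length - 1e-9, axis=1)
    ]
    return mesh, left, right_facets


def bar_traction_loads(mesh, left, right_facets, sigma=4.0):
    """Load-controlled confined bar: axial end traction ``sigma`` (N/mm^2)."""
    n = mesh.n_nodes
    return br.LoadCase(
        dirichlet=[(left, 0, 0.0), (np.arange(n), 1, 0.0)],
        tractions=[(right_facets, np.array([sigma, 0.0]))],
    )


@pytest.fixture(scope="session")
def bar():
    mesh, left, right = make_bar()
    return mesh, left, right


@pytest.fixture(scope="session")
def table_params():
    return br.MaterialParams()
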