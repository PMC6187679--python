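import numpy as np
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from spherotrap.geometry import (DOMAIN_MEDIUM, DOMAIN_SPHEROID,
                                 build_trap_geometry, default_config)
from spherotrap.meshing import BOUNDARY_TAGS, generate_mesh

VARIANTS = ["integrated_u", "micropost_u", "microwell"]


def _mesh(variant, D=400, resolution="test", **kw):
    if variant != "microwell":
        kw.setdefault("barrier_height", 400.0)
    cfg = default_config(variant, D, **kw)
    return generate_mesh(build_trap_geometry(cfg), resolution)


@pytest.mark.parametrize("variant", VARIANTS)
def test_all_boundary_tags_present(variant):
    m = _mesh(variant)
    for tag in BOUNDARY_TAGS:
        if variant == "microwell" and tag == "internal":
            # the submerged sphere touches only glass and medium: no
            # spheroid-PDMS contact exists in this trap
            continue
        assert len(m.facets[tag]) > 0, f"{variant}: no {tag} facets"


@pytest.mark.parametrize("variant", VARIANTS)
def test_domain_volumes_partition_bounding_solid(variant):
    m = _mesh(variant)
    solid = build_trap_geometry(m.config)
    total = sum(m.domain_volume(c) for c in (1, 2, 3, 4))
    # the microwell cavity has a curved footprint that the voxel mesh only
    # approximates; the channel+lid box itself partitions exactly
    rel = 0.02 if variant == "microwell" else 1e-9
    assert total == pytest.approx(solid.bounding_volume_um3() * 1e-18, rel=rel)
    assert (m.cell_volumes > 0).all()


def test_spheroid_volume_accuracy_improves_under_refinement():
    solid = build_trap_geometry(default_config("integrated_u", 500))
    exact = solid.spheroid_volume_um3() * 1e-18
    errs = {}
    for res in ("coarse", "fine"):
        m = generate_mesh(solid, res)
        errs[res] = abs(m.domain_volume(DOMAIN_SPHEROID) - exact) / exact
    assert errs["coarse"] < 0.02
    assert errs["fine"] < 0.02


def test_mesh_generation_is_deterministic():
    solid = build_trap_geometry(default_config("integrated_u", 300))
    a = generate_mesh(solid, "test", seed=1)
    b = generate_mesh(solid, "test", seed=1)
    assert np.array_equal(a.cells, b.cells)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.domain_tags, b.domain_tags)


@pytest.mark.parametrize("variant", VARIANTS)
def test_medium_connected_inlet_to_outlet(variant):
    m = _mesh(variant)
    med = m.cells_of_domain(DOMAIN_MEDIUM)
    pos = np.full(m.n_cells, -1)
    pos[med] = np.arange(len(med))
    # adjacency of medium cells via shared vertices (conforming mesh)
    rows, cols = [], []
    vert_cells = {}
    for li, ci in enumerate(med):
        for v in m.cells[ci]:
            vert_cells.setdefault(v, []).append(li)
    for group in vert_cells.values():
        for a in group:
            rows.extend([a] * len(group))
            cols.extend(group)
    g = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                      shape=(len(med), len(med)))
    n_comp, labels = connected_components(g, directed=False)
    inlet_cells = pos[m.facet_cells["inlet"][:, 0]]
    outlet_cells = pos[m.facet_cells["outlet"][:, 0]]
    assert len(set(labels[inlet_cells]) & set(labels[outlet_cells])) > 0


def test_interface_facets_separate_correct_domains():
    m = _mesh("integrated_u", 500, barrier_height=600.0)
    fc = m.facet_cells["spheroid_interface"]
    assert (m.domain_tags[fc[:, 0]] == DOMAIN_MEDIUM).all()
    assert (m.domain_tags[fc[:, 1]] == DOMAIN_SPHEROID).all()


def test_paper_resolution_matches_published_cell_count():
    """The study's grid-independent mesh had ~338k tetrahedra."""
    m = generate_mesh(build_trap_geometry(default_config("integrated_u", 500)),
                      "paper")
    assert 0.7 * 338220 <= m.n_cells <= 1.3 * 338220


def test_point_location_roundtrip(u500_test_mesh):
    m = u500_test_mesh
    rng = np.random.default_rng(7)
    take = rng.choice(m.n_cells, 200, replace=False)
    cents = m.vertices[m.cells[take]].mean(axis=1)
    found = m.locate_cells(cents)
    assert (found == take).all()
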