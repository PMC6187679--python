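"""Viability zone maps: proliferating, quiescent/hypoxic and necrotic tissue.

Spheroid tissue is labelled by comparing the local native concentration with
two viability thresholds. For oxygen the quiescent (hypoxic) boundary is a
partial pressure of 10 mmHg — about 0.01322 mM of dissolved oxygen — and the
necrotic boundary is pO₂ ≈ 0 mmHg; for glucose the corresponding levels are
0.5 mM and 0.2 mM. Zone sizes are reported as area fractions on the mid
x–z plane (the vertical streamwise symmetry plane through the spheroid
centre): the plane section is sampled on a dense polar grid and the field is
interpolated onto it, so the reported percentages are not quantized by the
mesh cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .geometry import DOMAIN_SPHEROID, GeometryConfig, TrapVariant
from .transport import ConcentrationField

__all__ = [
    "ZoneThresholds", "ZoneMap", "po2_to_conc", "classify",
    "midplane_fractions", "sensitivity",
]

LABEL_PROLIFERATING = 0
LABEL_QUIESCENT = 1
LABEL_NECROTIC = 2

_NECROTIC_EPS = 1e-6  # mM band for the "concentration near zero" label


@dataclass(frozen=True)
class ZoneThresholds:
    """Viability thresholds in native tissue concentration units (mM)."""

    species: str
    quiescent_c: float
    necrotic_c: float
    o2_solubility_alpha: float = C.O2_SOLUBILITY_ALPHA   # mM/mmHg

    def __post_init__(self):
        if not 0 <= self.necrotic_c <= self.quiescent_c:
            raise ValueError("need 0 <= necrotic_c <= quiescent_c")
        if self.o2_solubility_alpha <= 0:
            raise ValueError("o2_solubility_alpha must be positive")

    @classmethod
    def for_species(cls, name: str) -> "ZoneThresholds":
        if name == "oxygen":
            return cls("oxygen", C.O2_QUIESCENT_MM, C.O2_NECROTIC_MM)
        if name == "glucose":
            return cls("glucose", C.GLC_QUIESCENT_MM, C.GLC_NECROTIC_MM)
        raise ValueError(f"no default thresholds for species {name!r}")


def po2_to_conc(p_mmHg, alpha: float = C.O2_SOLUBILITY_ALPHA):
    """Convert oxygen partial pressure to dissolved concentration, c = α·p."""
    p = np.asarray(p_mmHg, dtype=float)
    if (p < 0).any():
        raise ValueError("partial pressure must be non-negative")
    out = alpha * p
    return float(out) if out.ndim == 0 else out


@dataclass
class ZoneMap:
    """Per-cell viability labels over the spheroid plus the source field."""

    field: ConcentrationField
    thresholds: ZoneThresholds
    cell_labels: np.ndarray          # per spheroid cell (global id order)
    spheroid_cells: np.ndarray       # global cell ids
    midplane: dict | None = None     # cached fraction summary

    def counts(self) -> dict[str, int]:
        return {
            "proliferating": int((self.cell_labels == LABEL_PROLIFERATING).sum()),
            "quiescent": int((self.cell_labels == LABEL_QUIESCENT).sum()),
            "necrotic": int((self.cell_labels == LABEL_NECROTIC).sum()),
        }


def classify(field: ConcentrationField,
             thresholds: ZoneThresholds | None = None) -> ZoneMap:
    """Label every spheroid cell by its viability zone.

    A cell is necrotic if its consumption was deactivated by the necrosis
    clamp or its native concentration sits within a small ε band of the
    necrotic threshold (exact zero is unreachable under Michaelis–Menten
    kinetics); quiescent if below the quiescent threshold; proliferating
    otherwise.
    """
    thresholds = thresholds or ZoneThresholds.for_species(field.species.name)
    dom = field.mesh.domain_tags[field.space.cell_ids]
    sph = dom == DOMAIN_SPHEROID
    c = field.native_cell_values()[sph]
    clamped = field.clamp_mask[sph]
    labels = np.full(len(c), LABEL_PROLIFERATING, dtype=np.int8)
    labels[c <= thresholds.quiescent_c] = LABEL_QUIESCENT
    labels[clamped | (c <= thresholds.necrotic_c + _NECROTIC_EPS)] = LABEL_NECROTIC
    return ZoneMap(
        field=field, thresholds=thresholds, cell_labels=labels,
        spheroid_cells=field.space.cell_ids[sph],
    )


def midplane_fractions(zone_map: ZoneMap, config: GeometryConfig | None = None,
                       n_r: int = 160, n_theta: int = 360) -> dict[str, float]:
    """Zone area percentages on the mid x–z plane of the spheroid.

    The spheroid disc on the vertical symmetry plane (y = width/2) is
    sampled on a polar quadrature grid; each point is labelled from the
    interpolated concentration (and the clamp mask), and the label areas are
    accumulated with the polar weights. Percentages refer to the resolvable
    disc area and sum to 100.
    """
    field = zone_map.field
    config = config or field.mesh.config
    th = zone_map.thresholds
    cx, cy, cz = config.spheroid_center
    if config.trap_variant != TrapVariant.MICROWELL:
        cx, cz = cx - config.contact_embed, cz + config.contact_embed
    else:
        cx = cx - config.contact_embed
    if abs(cy - config.channel_width / 2.0) > config.spheroid_radius:
        raise ValueError("mid plane does not intersect the spheroid")
    R = config.spheroid_radius * 1e-6
    rr = (np.arange(n_r) + 0.5) / n_r * R
    tt = (np.arange(n_theta) + 0.5) / n_theta * 2 * np.pi
    Rg, Tg = np.meshgrid(rr, tt, indexing="ij")
    pts = np.column_stack([
        cx * 1e-6 + (Rg * np.cos(Tg)).ravel(),
        np.full(Rg.size, cy * 1e-6),
        cz * 1e-6 + (Rg * np.sin(Tg)).ravel(),
    ])
    weights = (Rg * (R / n_r) * (2 * np.pi / n_theta)).ravel()

    c = field.transformed_at(pts) * field.species.S_tissue
    cid = field.mesh.locate_cells(pts)
    clamped_set = np.zeros(field.mesh.n_cells, dtype=bool)
    clamped_set[zone_map.field.clamped_cells] = True
    in_clamped = np.where(cid >= 0, clamped_set[np.clip(cid, 0, None)], False)

    ok = np.isfinite(c)
    labels = np.full(pts.shape[0], -1, dtype=np.int8)
    labels[ok] = LABEL_PROLIFERATING
    labels[ok & (c <= th.quiescent_c)] = LABEL_QUIESCENT
    labels[(ok & (c <= th.necrotic_c + _NECROTIC_EPS)) | (ok & in_clamped)] = \
        LABEL_NECROTIC

    tot = weights[ok].sum()
    if tot <= 0:
        raise ValueError("mid plane sampling found no resolvable area")
    frac = {
        "proliferating": 100.0 * weights[labels == LABEL_PROLIFERATING].sum() / tot,
        "quiescent": 100.0 * weights[labels == LABEL_QUIESCENT].sum() / tot,
        "necrotic": 100.0 * weights[labels == LABEL_NECROTIC].sum() / tot,
    }
    zone_map.midplane = frac
    return frac


def sensitivity(case_a: ZoneMap, case_b: ZoneMap) -> float:
    """Percent change of the combined quiescent + necrotic mid-plane area.

    Returns ``100·(A_b − A_a)/A_a`` where A is the quiescent + necrotic
    percentage of the spheroid's mid-plane disc; negative values mean the
    deficient region shrank from case a to case b.
    """
    fa = case_a.midplane or midplane_fractions(case_a)
    fb = case_b.midplane or midplane_fractions(case_b)
    Aa = fa["quiescent"] + fa["necrotic"]
    Ab = fb["quiescent"] + fb["necrotic"]
    if Aa <= 0:
        raise ValueError("reference case has no quiescent or necrotic area")
    return 100.0 * (Ab - Aa) / Aa
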