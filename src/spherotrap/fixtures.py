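"""Named study cases: geometry + operating conditions, ready to run.

Every figure-level scenario of the study is available as a named fixture so
that downstream stages (flow, transport, zones, transients) can be driven
without any external input. A fixture bundles the geometry configuration,
a generated mesh at a chosen resolution and the operating conditions
(flow rate and inlet concentrations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import GeometryConfig, TrapVariant, build_trap_geometry, default_config
from .meshing import Mesh, generate_mesh

__all__ = ["StudyCase", "make_fixture", "list_cases"]


@dataclass
class StudyCase:
    """A runnable study scenario."""

    name: str
    config: GeometryConfig
    mesh: Mesh
    conditions: dict = field(default_factory=dict)

    @property
    def Q_uL_min(self) -> float:
        return self.conditions["Q_uL_min"]


def _u(D=500.0, **kw):
    return default_config(TrapVariant.INTEGRATED_U, D, **kw)


# case -> (config factory kwargs, conditions)
_REGISTRY: dict[str, tuple[GeometryConfig, dict]] = {}


def _register(name, config, **conditions):
    _REGISTRY[name] = (config, conditions)


# diameter sweep at Q = 5, c0_O2 = 0.2 mM, c0_glc = 11 mM
for D in (200, 300, 400, 500):
    _register(f"fig4_D{D}", _u(D), Q_uL_min=5.0, c0_O2_mM=0.2, c0_glucose_mM=11.0)

# flow-rate sweep at D = 500
for Q in (5, 10, 15, 20):
    _register(f"fig5_Q{Q}", _u(500), Q_uL_min=float(Q), c0_O2_mM=0.2,
              c0_glucose_mM=11.0)

# inlet-concentration sweeps at D = 500, Q = 5
for c0 in (0.02, 0.05, 0.1, 0.13, 0.2):
    _register(f"fig7_O2_{c0:g}", _u(500), Q_uL_min=5.0, c0_O2_mM=c0)
for c0 in (0.7, 1.0, 3.0, 5.5, 11.0):
    _register(f"fig7_glc_{c0:g}", _u(500), Q_uL_min=5.0, c0_glucose_mM=c0)

# oxygen zone sensitivity around (D=500, Q=5, c0=0.1)
_register("fig8_left", _u(500), Q_uL_min=5.0, c0_O2_mM=0.1)
_register("fig8_D480", _u(480), Q_uL_min=5.0, c0_O2_mM=0.1)
_register("fig8_Q10", _u(500), Q_uL_min=10.0, c0_O2_mM=0.1)
_register("fig8_c008", _u(500), Q_uL_min=5.0, c0_O2_mM=0.08)

# glucose zone sensitivity; the reference inlet level is the largest of the
# operating range for which deficiency zones exist (1 mM)
_register("fig9_ref", _u(500), Q_uL_min=5.0, c0_glucose_mM=1.0)
_register("fig9_D480", _u(480), Q_uL_min=5.0, c0_glucose_mM=1.0)
_register("fig9_Q10", _u(500), Q_uL_min=10.0, c0_glucose_mM=1.0)
_register("fig9_c08", _u(500), Q_uL_min=5.0, c0_glucose_mM=0.8)

# trap-type comparison, D = 400, equal trap height 400 µm
_f10 = dict(Q_uL_min=5.0, c0_O2_mM=0.2, c0_glucose_mM=0.7)
_register("fig10_integrated_u",
          default_config(TrapVariant.INTEGRATED_U, 400, barrier_height=400.0),
          **_f10)
_register("fig10_micropost_u",
          default_config(TrapVariant.MICROPOST_U, 400, barrier_height=400.0),
          **_f10)
_register("fig10_microwell",
          default_config(TrapVariant.MICROWELL, 400), **_f10)

# no-flow glucose depletion transients
for D in (200, 300, 400, 500):
    _register(f"fig11_D{D}", _u(D), Q_uL_min=5.0, c0_glucose_mM=11.0,
              transient=True)


def list_cases() -> list[str]:
    return sorted(_REGISTRY) + ["fig10_all"]


def make_fixture(case_name: str, resolution: str = "test"):
    """Build the named study case at the requested mesh resolution.

    Returns a :class:`StudyCase`; ``"fig10_all"`` returns the list of the
    three trap-comparison cases. Unknown names raise ``KeyError``.
    """
    if case_name == "fig10_all":
        return [make_fixture(f"fig10_{v}", resolution)
                for v in ("microwell", "integrated_u", "micropost_u")]
    if case_name not in _REGISTRY:
        raise KeyError(
            f"unknown study case {case_name!r}; known: {', '.join(list_cases())}")
    config, conditions = _REGISTRY[case_name]
    mesh = generate_mesh(build_trap_geometry(config), resolution)
    return StudyCase(name=case_name, config=config, mesh=mesh,
                     conditions=dict(conditions))
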