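"""Canonical simulation protocols for the three study geometries.

These configurations define the package's reference experiments:

* ``bead_2d_protocol`` — five 1-um-bead-like point emitters on a single
  plane ~100 um behind a strongly scattering thin layer; global demixing,
  linear relative phases.
* ``two_plane_protocol`` — beads split between depth planes 80 and 95 um
  behind the layer; tiled demixing with stitched medium.
* ``spiral_protocol`` — twenty foci on a descending spiral (two full
  turns, 10 um axial span); tiled demixing, the most demanding geometry.

Grid sizes are chosen so the collection cone of the deepest source fits
inside the simulated field of view (the periodic grid would otherwise
alias the cone onto itself): 76.8 um of field for the ~100 um bead
geometries, 51.2 um for the shallower spiral.  All stage seeds derive
from one master seed.
"""

from __future__ import annotations

from .pipeline import PipelineConfig

__all__ = ["bead_2d_protocol", "two_plane_protocol", "spiral_protocol"]


def bead_2d_protocol(seed: int = 1, n_masks: int = 120) -> PipelineConfig:
    """Single-depth five-bead object ~100 um behind the layer (192 px)."""
    cfg = PipelineConfig(sections={
        "grid": {"n_x": 192, "n_y": 192},
        "fixture": {"kind": "beads", "n_beads": 5, "plane_depths": [100.0],
                    "min_separation_um": 6.0, "lateral_extent_um": 24.0},
        "masks": {"count": n_masks},
        "geometry": {"focus_distance_um": 100.0},
        "retrieval": {"n_states": 5},
        "locate": {"z_min_um": 61.0, "z_max_um": 141.0},
        "demix": {"mode": "global"},
        "medium": {"phase_model": "linear"},
        "reconstruct": {"z_min_um": -6.0, "z_max_um": 6.0, "z_step_um": 0.25,
                        "rel_threshold": 0.5},
    })
    return cfg.with_seed(seed)


def two_plane_protocol(seed: int = 1, n_masks: int = 120) -> PipelineConfig:
    """Beads on two depth planes (80 and 95 um) behind the layer (192 px)."""
    cfg = PipelineConfig(sections={
        "grid": {"n_x": 192, "n_y": 192},
        "fixture": {"kind": "beads", "n_beads": 4,
                    "plane_depths": [80.0, 95.0],
                    "min_separation_um": 7.0, "lateral_extent_um": 24.0},
        "masks": {"count": n_masks},
        "geometry": {"focus_distance_um": 90.0},
        "retrieval": {"n_states": 4},
        "locate": {"z_min_um": 51.0, "z_max_um": 131.0},
        "demix": {"mode": "tiled", "rows": 3, "cols": 3, "overlap": 0.25},
        "medium": {"phase_model": "linear"},
        "reconstruct": {"z_min_um": -12.0, "z_max_um": 12.0,
                        "z_step_um": 0.4, "rel_threshold": 0.3},
    })
    return cfg.with_seed(seed)


def spiral_protocol(seed: int = 1, n_masks: int = 200) -> PipelineConfig:
    """Twenty spiral foci over a 10 um axial span behind the layer (128 px)."""
    cfg = PipelineConfig(sections={
        "grid": {"n_x": 128, "n_y": 128},
        "fixture": {"kind": "spiral", "z_base_um": 55.0},
        "masks": {"count": n_masks},
        "geometry": {"focus_distance_um": 60.0},
        "retrieval": {"n_states": 20},
        "locate": {"z_min_um": 21.0, "z_max_um": 101.0},
        "demix": {"mode": "tiled", "rows": 3, "cols": 3, "overlap": 0.25,
                  "max_iters": 150, "restarts": 2},
        "medium": {"phase_model": "linear"},
        "reconstruct": {"z_min_um": -5.0, "z_max_um": 5.0, "z_step_um": 0.2,
                        "rel_threshold": 0.5, "merge_radius_um": 0.8},
    })
    return cfg.with_seed(seed)
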