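"""Restructured network variants built from a distance-rule baseline and a
residual field.

Each builder starts from the power-law baseline K (weights strictly
distance-dependent) and manipulates only the *positive* residual tail — the
connections stronger than the distance rule predicts:

- restore the top fraction of positive residuals at their original edges;
- shuffle the positive residual values onto random edges;
- relocate the total positive residual mass onto edges in a distance window
  (proximal or distal), split equally;
- relocate it onto the longest edges above a length cutoff.

All relocation variants conserve total network strength: they hold the sum
of weights equal to baseline-plus-positive-residual mass, so differences in
dynamics are attributable to *where* the strong connections sit, not to how
much coupling the network carries.  Negative residuals are never moved or
restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distance_model import ResidualField

__all__ = ["VariantSpec", "build_power_law_network",
           "add_top_residual_fraction", "shuffle_residuals",
           "relocate_residuals_window", "relocate_longest_fraction",
           "build_variant", "LONGEST_EDGE_CUTOFFS_UM"]

# length cutoffs (micrometres) for restoring residuals onto the longest
# 1-90% of edges of the mouse whole-brain network
LONGEST_EDGE_CUTOFFS_UM = (9404.0, 8830.0, 8470.0, 8175.0, 7946.0, 7168.0,
                           6265.0, 5626.0, 5063.0, 4521.0, 3992.0, 3455.0,
                           2867.0, 2147.0)

_KINDS = ("power_law_only", "top_residual_fraction", "shuffled_residuals",
          "relocate_window", "relocate_longest_fraction")


@dataclass(frozen=True)
class VariantSpec:
    """Declarative description of a network variant (used by the pipeline)."""

    kind: str
    fraction_or_percentile: float | None = None
    distance_window: tuple[float, float] | None = None
    cutoff_length: float | None = None
    seed: int = 0
    name: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.fraction_or_percentile is not None and not (
                0 < self.fraction_or_percentile <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        if self.distance_window is not None:
            lo, hi = self.distance_window
            if not lo < hi:
                raise ValueError(f"empty distance window ({lo}, {hi})")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        return self.kind


def build_power_law_network(baseline: np.ndarray) -> np.ndarray:
    """The strictly distance-dependent network: the baseline itself."""
    k = np.array(baseline, dtype=float)
    np.fill_diagonal(k, 0.0)
    return k


def _positive_entries(residual_field: ResidualField):
    mask = residual_field.positive_mask
    if not mask.any():
        raise ValueError("residual field has no positive entries")
    idx = np.argwhere(mask)
    vals = residual_field.residuals[mask]
    return idx, vals


def add_top_residual_fraction(baseline: np.ndarray,
                              residual_field: ResidualField,
                              fraction: float) -> np.ndarray:
    """Restore the strongest fraction of positive residuals in place.

    The top ``fraction`` of positive residuals (by magnitude) are added back
    at their original edges; ties at the threshold are all included.
    ``fraction=1`` restores the full positive tail.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    idx, vals = _positive_entries(residual_field)
    m = int(np.ceil(fraction * len(vals) - 1e-12))
    threshold = np.sort(vals)[::-1][m - 1]
    keep = vals >= threshold
    out = build_power_law_network(baseline)
    out[idx[keep, 0], idx[keep, 1]] += vals[keep]
    return out


def shuffle_residuals(baseline: np.ndarray, residual_field: ResidualField,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Scatter the positive residual values onto random distinct edges.

    The multiset of positive residual values is preserved; destinations are
    drawn uniformly without replacement from all off-diagonal edges, so the
    strong connections remain spread across all edge lengths but lose their
    data-driven locations.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    _, vals = _positive_entries(residual_field)
    out = build_power_law_network(baseline)
    n = out.shape[0]
    edges = np.argwhere(~np.eye(n, dtype=bool))
    if len(vals) > len(edges):
        raise ValueError(
            f"{len(vals)} residuals but only {len(edges)} off-diagonal edges"
        )
    pick = rng.choice(len(edges), size=len(vals), replace=False)
    dest = edges[pick]
    out[dest[:, 0], dest[:, 1]] += vals
    return out


def relocate_residuals_window(baseline: np.ndarray,
                              residual_field: ResidualField,
                              distances: np.ndarray,
                              window: tuple[float, float]) -> np.ndarray:
    """Distribute the total positive residual mass equally over the edges
    whose length falls in ``[d_min, d_max)``.

    Used with a short window this concentrates the extra strength on
    proximal connections, with a long window on distal ones; either way the
    total network strength matches the data network's.
    """
    d_min, d_max = window
    if not d_min < d_max:
        raise ValueError(f"empty distance window ({d_min}, {d_max})")
    _, vals = _positive_entries(residual_field)
    out = build_power_law_network(baseline)
    d = np.asarray(distances, dtype=float)
    in_window = (d >= d_min) & (d < d_max) & ~np.eye(out.shape[0], dtype=bool)
    m = int(in_window.sum())
    if m == 0:
        raise ValueError(f"no off-diagonal edges in window [{d_min}, {d_max})")
    out[in_window] += vals.sum() / m
    return out


def relocate_longest_fraction(baseline: np.ndarray,
                              residual_field: ResidualField,
                              distances: np.ndarray,
                              cutoff_length: float) -> np.ndarray:
    """Distribute the positive residual mass over edges longer than
    ``cutoff_length`` (equal split)."""
    d = np.asarray(distances, dtype=float)
    off = ~np.eye(d.shape[0], dtype=bool)
    if not (d[off].min() <= cutoff_length <= d[off].max()):
        raise ValueError(
            f"cutoff {cutoff_length} outside observed edge-length range "
            f"[{d[off].min():.1f}, {d[off].max():.1f}]"
        )
    return relocate_residuals_window(baseline, residual_field, d,
                                     (cutoff_length, np.inf))


def build_variant(spec: VariantSpec, baseline: np.ndarray,
                  residual_field: ResidualField,
                  distances: np.ndarray) -> np.ndarray:
    """Dispatch a :class:`VariantSpec` to the corresponding builder."""
    if spec.kind == "power_law_only":
        return build_power_law_network(baseline)
    if spec.kind == "top_residual_fraction":
        return add_top_residual_fraction(baseline, residual_field,
                                         spec.fraction_or_percentile)
    if spec.kind == "shuffled_residuals":
        return shuffle_residuals(baseline, residual_field, spec.seed)
    if spec.kind == "relocate_window":
        return relocate_residuals_window(baseline, residual_field, distances,
                                         spec.distance_window)
    if spec.kind == "relocate_longest_fraction":
        return relocate_longest_fraction(baseline, residual_field, distances,
                                         spec.cutoff_length)
    raise ValueError(f"unknown variant kind {spec.kind!r}")
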