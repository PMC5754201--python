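"""Thresholded intensity, volume and count metrics for one specimen.

Implements the niche morphometrics: summed supra-threshold glial membrane
intensity, its ratio to the NSC count (a proxy for per-lineage membrane
abundance), thresholded neuronal volume with control-centred
normalization, and marker-positive nucleus counting by 3D connected
components. One threshold policy per role is resolved once per experiment
and kept constant across every condition being compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

from .stack_io import ImageStack, RegionOfInterest

__all__ = [
    "ThresholdPolicy",
    "NicheMetrics",
    "membrane_intensity",
    "membrane_to_nsc_ratio",
    "count_nuclei",
    "marker_positive_fraction",
    "neuronal_volume",
    "normalize_volumes",
    "compute_niche_metrics",
    "read_manual_counts",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the intensity threshold for one role's channel is chosen.

    mode:
        ``"absolute"`` — *value* is the threshold in intensity units;
        ``"quantile"`` — *value* in [0, 1], threshold at that intensity
        quantile of the channel within the ROI;
        ``"otsu"`` — Otsu's method on the channel within the ROI
        (*value* ignored).

    The same resolved policy must be applied to every condition of an
    experiment: resolve on pooled control data once, then freeze.
    """

    role: str
    mode: str = "absolute"
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "otsu", "quantile"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if self.mode == "quantile" and not (0.0 <= self.value <= 1.0):
            raise ValueError(f"quantile must lie in [0, 1]; got {self.value}")

    def resolve(
        self, stack: ImageStack, roi: RegionOfInterest | None = None
    ) -> float:
        """Resolve the policy to an absolute intensity threshold on *stack*."""
        if self.mode == "absolute":
            if not np.isfinite(self.value):
                raise ValueError("absolute threshold must be finite")
            return float(self.value)
        if roi is None:
            roi = RegionOfInterest.full(stack)
        channel = stack.channel(self.role)[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
        if self.mode == "quantile":
            return float(np.quantile(channel, self.value))
        return float(threshold_otsu(channel.ravel()))


@dataclass
class NicheMetrics:
    """Per-specimen morphometric readout (tidy-table row)."""

    specimen_id: str
    condition: str
    membrane_intensity: float
    nsc_count: int
    ratio: float | None
    neuron_volume: float
    marker_counts: dict[str, int] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "specimen_id": self.specimen_id,
            "condition": self.condition,
            "membrane_intensity": self.membrane_intensity,
            "nsc_count": self.nsc_count,
            "ratio": self.ratio,
            "neuron_volume": self.neuron_volume,
        }
        for marker, count in sorted(self.marker_counts.items()):
            row[f"count_{marker}"] = count
        return row


def _masked_channel(
    stack: ImageStack,
    role: str,
    roi: RegionOfInterest | None,
    policy: ThresholdPolicy,
    background: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Channel values within ROI (background-subtracted) and their supra-threshold mask."""
    if roi is None:
        roi = RegionOfInterest.full(stack)
    roi.validate_for(stack)
    channel = stack.channel(role)[:, roi.y0 : roi.y1, roi.x0 : roi.x1]
    if background:
        channel = np.clip(channel - background, 0.0, None)
    threshold = policy.resolve(stack, roi)
    return channel, channel >= threshold


def membrane_intensity(
    stack: ImageStack,
    roi: RegionOfInterest | None = None,
    policy: ThresholdPolicy | None = None,
    statistic: str = "sum",
    background: float = 0.0,
) -> float:
    """Total supra-threshold glial-channel signal within the ROI.

    ``statistic="sum"`` (default) integrates the intensity of voxels at or
    above threshold; ``statistic="count"`` counts them instead, exposed
    for sensitivity analysis. ``background`` is an optional constant
    offset subtracted (and clipped at zero) before thresholding.
    """
    if policy is None:
        policy = ThresholdPolicy(role="glia", mode="absolute", value=0.0)
    values, mask = _masked_channel(stack, policy.role or "glia", roi, policy, background)
    if statistic == "sum":
        return float(values[mask].sum())
    if statistic == "count":
        return float(mask.sum())
    raise ValueError(f"unknown statistic {statistic!r}")


def membrane_to_nsc_ratio(membrane_intensity: float, nsc_count: int) -> float:
    """Membrane signal per NSC: supra-threshold glial intensity / NSC count."""
    if nsc_count <= 0:
        raise ValueError("ratio undefined: NSC count must be positive")
    return membrane_intensity / nsc_count


def count_nuclei(
    stack: ImageStack,
    role: str,
    policy: ThresholdPolicy,
    min_volume: int = 1,
    roi: RegionOfInterest | None = None,
) -> int:
    """Count 26-connected supra-threshold components with >= *min_volume* voxels.

    Touching nuclei merge into one component — a documented limitation;
    manual counts can be supplied via CSV instead.
    """
    _, mask = _masked_channel(stack, role, roi, policy)
    labels = label(mask, connectivity=3)  # 26-connectivity in 3D
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_volume))


def marker_positive_fraction(positive: int, total: int) -> float:
    """Fraction of marker-positive cells (e.g. mitotic index, TUNEL+ fraction)."""
    if total <= 0:
        raise ValueError("total count must be positive")
    if not (0 <= positive <= total):
        raise ValueError(f"need 0 <= positive <= total; got {positive}/{total}")
    return positive / total


def neuronal_volume(
    stack: ImageStack,
    roi: RegionOfInterest | None = None,
    policy: ThresholdPolicy | None = None,
    voxel_volume: float | None = None,
) -> float:
    """Total supra-threshold neuron-channel volume within the ROI.

    Reported as voxel count when *voxel_volume* is unknown, otherwise
    scaled to physical units.
    """
    if policy is None:
        policy = ThresholdPolicy(role="neuron", mode="absolute", value=0.0)
    _, mask = _masked_channel(stack, policy.role or "neuron", roi, policy)
    count = float(mask.sum())
    return count * voxel_volume if voxel_volume is not None else count


def normalize_volumes(values, control_values) -> np.ndarray:
    """Centre the control group at one: divide every value by the control mean."""
    values = np.asarray(values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ValueError("control group is empty")
    mean = control.mean()
    if mean <= 0:
        raise ValueError("control mean must be positive")
    return values / mean


def compute_niche_metrics(
    stack: ImageStack,
    roi: RegionOfInterest | None = None,
    glia_policy: ThresholdPolicy | None = None,
    nsc_policy: ThresholdPolicy | None = None,
    neuron_policy: ThresholdPolicy | None = None,
    min_nucleus_volume: int = 1,
    nsc_count: int | None = None,
) -> NicheMetrics:
    """All morphometrics for one specimen.

    *nsc_count* overrides the automated connected-component count with an
    externally supplied (e.g. manual) count.
    """
    glia_policy = glia_policy or ThresholdPolicy(role="glia")
    nsc_policy = nsc_policy or ThresholdPolicy(role="nsc")
    neuron_policy = neuron_policy or ThresholdPolicy(role="neuron")

    intensity = membrane_intensity(stack, roi, glia_policy)
    if nsc_count is None:
        nsc_count = count_nuclei(stack, "nsc", nsc_policy, min_nucleus_volume, roi)
    volume = neuronal_volume(stack, roi, neuron_policy)
    ratio = membrane_to_nsc_ratio(intensity, nsc_count) if nsc_count > 0 else None
    return NicheMetrics(
        specimen_id=stack.specimen_id,
        condition=stack.condition,
        membrane_intensity=intensity,
        nsc_count=int(nsc_count),
        ratio=ratio,
        neuron_volume=volume,
    )


def read_manual_counts(path: str | Path):
    """Read a manual-count CSV with columns ``specimen_id, marker, count``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"specimen_id", "marker", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"manual-count CSV needs columns {sorted(required)}")
    if (df["count"] < 0).any():
        raise ValueError("manual counts must be non-negative")
    return df
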