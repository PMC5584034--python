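"""Time-phase binning of a continuous cone-beam acquisition.

The scan is split into ``T`` phases of equal duration; phase ``t``
(1-based) is centered at time ``(t - 1/2) * duration / T``.  Each phase
is reconstructed from the contiguous block of projections whose gantry
angle lies within half the angular window of the phase-center angle,
clamped to the acquired range, so adjacent windows overlap whenever the
window exceeds the phase spacing (e.g. 200-degree windows for TV-only
reconstruction, 90-degree windows for prior-image or time-chain
regularized reconstruction of a 9-phase, 360-degree scan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .projector import ProjectionSet

__all__ = ["PhaseBinning", "assign_phases"]


@dataclass(frozen=True)
class PhaseBinning:
    """Mapping from phase index to its contiguous projection window."""

    n_phases: int
    window_extent: float  # degrees
    phase_center_times: np.ndarray  # seconds, shape (T,)
    phase_center_angles: np.ndarray  # degrees, shape (T,)
    windows: tuple[tuple[int, int], ...]  # half-open index ranges

    def indices(self, t: int) -> np.ndarray:
        """Projection indices of phase ``t`` (0-based phase index)."""
        lo, hi = self.windows[t]
        return np.arange(lo, hi)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_phases": self.n_phases,
                "window_extent_deg": self.window_extent,
                "phase_center_times_s": self.phase_center_times.tolist(),
                "phase_center_angles_deg": self.phase_center_angles.tolist(),
                "windows": [list(w) for w in self.windows],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "PhaseBinning":
        d = json.loads(text)
        return cls(
            n_phases=d["n_phases"],
            window_extent=d["window_extent_deg"],
            phase_center_times=np.asarray(d["phase_center_times_s"]),
            phase_center_angles=np.asarray(d["phase_center_angles_deg"]),
            windows=tuple(tuple(w) for w in d["windows"]),
        )


def assign_phases(
    projections: ProjectionSet,
    n_phases: int,
    window_extent: float,
) -> PhaseBinning:
    """Assign each of ``n_phases`` phases its angular projection window.

    Phase centers are equally spaced in acquisition time; the window of
    a phase collects the projections whose angle falls in
    ``[center - extent/2, center + extent/2)``, intersected with the
    acquired range (first/last windows are therefore asymmetric).
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    if window_extent <= 0:
        raise ValueError("window extent must be positive")
    times = projections.timestamps
    angles = projections.angles
    if len(times) < 2:
        raise ValueError("need at least 2 projections")
    dt = times[1] - times[0]
    duration = times[-1] - times[0] + dt
    centers_t = times[0] + (np.arange(n_phases) + 0.5) * duration / n_phases
    centers_a = np.interp(centers_t, times, angles)

    windows = []
    for ca in centers_a:
        inside = (angles >= ca - window_extent / 2.0) & (
            angles < ca + window_extent / 2.0
        )
        idx = np.nonzero(inside)[0]
        if idx.size == 0:
            raise ValueError("window contains no projections")
        windows.append((int(idx[0]), int(idx[-1]) + 1))
    return PhaseBinning(
        n_phases=n_phases,
        window_extent=float(window_extent),
        phase_center_times=centers_t,
        phase_center_angles=centers_a,
        windows=tuple(windows),
    )
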