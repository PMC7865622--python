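"""Derived kinematic signals: total acceleration and exerted force.

Two per-sample signals augment the nine raw IMU channels.  Total
acceleration is the Euclidean norm of the three accelerometer axes, making
it independent of how the sensor is strapped to the wrist; exerted force is
Newton's second law applied to the dumbbell mass, F = m * a, using the
total acceleration as ``a``.  Inputs are assumed gravity-compensated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["total_acceleration", "exerted_force", "add_derived_signals", "DERIVED_SIGNALS"]

DERIVED_SIGNALS = ("total_acceleration", "exerted_force")


def total_acceleration(acc_x, acc_y, acc_z) -> np.ndarray:
    """Elementwise Euclidean norm sqrt(ax^2 + ay^2 + az^2), in m/s^2."""
    ax = np.asarray(acc_x, dtype=float)
    ay = np.asarray(acc_y, dtype=float)
    az = np.asarray(acc_z, dtype=float)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError(
            f"accelerometer channels must have equal length, got "
            f"{ax.shape}, {ay.shape}, {az.shape}"
        )
    return np.sqrt(ax * ax + ay * ay + az * az)


def exerted_force(mass: float, accel) -> np.ndarray:
    """Elementwise F = m * a, in N for mass in kg and acceleration in m/s^2."""
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    return mass * np.asarray(accel, dtype=float)


def add_derived_signals(samples: pd.DataFrame, dumbbell_mass: float) -> pd.DataFrame:
    """Return a copy of the sample table with the two derived columns appended."""
    out = samples.copy()
    total = total_acceleration(out["acc_x"], out["acc_y"], out["acc_z"])
    out["total_acceleration"] = total
    out["exerted_force"] = exerted_force(dumbbell_mass, total)
    return out
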