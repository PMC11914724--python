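"""12-lead ECG signal container and lead algebra.

The standard 12-lead ECG carries only 8 independent channels: the four
derived limb leads are fixed linear combinations of leads I and II
(Einthoven's law and the Goldberger relations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The 8 linearly independent leads, in model-input order.
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Leads derivable from I and II; excluded from model inputs.
DERIVED_LEADS: tuple[str, ...] = ("III", "aVR", "aVL", "aVF")


def derive_augmented_leads(
    lead_i: np.ndarray, lead_ii: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Compute leads III, aVR, aVL, aVF from leads I and II.

    III = II - I, aVR = -(I + II)/2, aVL = I - II/2, aVF = II - I/2.

    Returns
    -------
    (III, aVR, aVL, aVF) : tuple of arrays, same shape as the inputs.
    """
    lead_i = np.asarray(lead_i, dtype=float)
    lead_ii = np.asarray(lead_ii, dtype=float)
    if lead_i.shape != lead_ii.shape:
        raise ValueError(
            f"lead shapes differ: I is {lead_i.shape}, II is {lead_ii.shape}"
        )
    lead_iii = lead_ii - lead_i
    avr = -(lead_i + lead_ii) / 2.0
    avl = lead_i - lead_ii / 2.0
    avf = lead_ii - lead_i / 2.0
    return lead_iii, avr, avl, avf


@dataclass
class ECGSignal:
    """A multi-lead ECG: per-lead sample arrays in mV at a common rate.

    Parameters
    ----------
    samples : (n_leads, n_samples) float array, millivolts.
    fs : sampling frequency in Hz.
    lead_names : lead identifiers, one per row of ``samples``.
    """

    samples: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = LEAD_NAMES

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.lead_names = tuple(self.lead_names)
        if self.samples.shape[0] != len(self.lead_names):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.lead_names)} lead names"
            )
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite sample values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        try:
            idx = self.lead_names.index(name)
        except ValueError:
            raise KeyError(f"lead {name!r} not present (have {self.lead_names})")
        return self.samples[idx]

    def copy(self) -> "ECGSignal":
        return ECGSignal(self.samples.copy(), self.fs, self.lead_names)

    @classmethod
    def from_independent(
        cls, independent: np.ndarray, fs: float
    ) -> "ECGSignal":
        """Build the full 12-lead signal from the 8 independent leads.

        ``independent`` rows follow :data:`INDEPENDENT_LEADS` order
        (I, II, V1..V6); III/aVR/aVL/aVF are derived, never simulated.
        """
        independent = np.atleast_2d(np.asarray(independent, dtype=float))
        if independent.shape[0] != 8:
            raise ValueError(f"expected 8 independent leads, got {independent.shape[0]}")
        lead_i, lead_ii = independent[0], independent[1]
        lead_iii, avr, avl, avf = derive_augmented_leads(lead_i, lead_ii)
        rows = {
            "I": lead_i, "II": lead_ii, "III": lead_iii,
            "aVR": avr, "aVL": avl, "aVF": avf,
        }
        for k, name in enumerate(INDEPENDENT_LEADS[2:]):
            rows[name] = independent[2 + k]
        samples = np.stack([rows[name] for name in LEAD_NAMES])
        return cls(samples, fs)

    # -- persistence: one CSV per record, lead columns, fs in the header --

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.samples.T, columns=list(self.lead_names))
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={self.fs}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ECGSignal":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# fs_hz="):
                raise ValueError(f"{path}: missing fs header line")
            fs = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        return cls(df.to_numpy().T, fs, tuple(df.columns))
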