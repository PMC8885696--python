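"""Labeled spectra collections for the viability classification task."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import PermittivitySpectrum, restrict_band

#: Ischemic duration (hours) at or above which a segment is non-viable.
VIABILITY_THRESHOLD_H = 4.0

VIABLE, NONVIABLE = "viable", "nonviable"


def viability_label(ischemia_h: float) -> str:
    """Binary viability from elapsed ischemic hours (< 4 h => viable)."""
    return VIABLE if ischemia_h < VIABILITY_THRESHOLD_H else NONVIABLE


@dataclass
class LabeledDataset:
    """Spectra with binary viability labels and grouping keys.

    ``labels`` holds {"viable", "nonviable"}; ``group_keys`` is the
    (subject_id, case_id) pair of each spectrum, for group-aware splitting.
    """

    spectra: list[PermittivitySpectrum]
    labels: list[str]
    group_keys: list[tuple[str, int]]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.spectra) == len(self.labels) == len(self.group_keys)):
            raise ValueError("spectra, labels and group_keys must have equal length")

    def __len__(self):
        return len(self.spectra)

    @property
    def y(self) -> np.ndarray:
        """Labels as 0/1 with non-viable = 1 (the positive class)."""
        return np.array([1 if l == NONVIABLE else 0 for l in self.labels])

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            [self.spectra[i] for i in idx],
            [self.labels[i] for i in idx],
            [self.group_keys[i] for i in idx],
        )

    def filter_phase(self, *phases: str) -> "LabeledDataset":
        idx = [i for i, s in enumerate(self.spectra) if s.meta and s.meta.phase in phases]
        return self.subset(idx)

    def restrict_band(self, f_min: float, f_max: float) -> "LabeledDataset":
        return LabeledDataset(
            [restrict_band(s, f_min, f_max) for s in self.spectra],
            list(self.labels),
            list(self.group_keys),
            list(self.provenance),
        )

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack spectra to (n, T, 2) sequences of (eps', eps'') and 0/1 labels.

        Requires all spectra to share one grid.
        """
        g0 = self.spectra[0].grid
        for s in self.spectra[1:]:
            if s.grid != g0:
                raise ValueError("all spectra must share one frequency grid")
        X = np.stack(
            [np.column_stack([s.eps_real, s.eps_imag]) for s in self.spectra]
        )
        return X, self.y

    def labels_frame(self) -> pd.DataFrame:
        rows = []
        for s, lab in zip(self.spectra, self.labels):
            m = s.meta
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "case_id": m.case_id,
                    "phase": m.phase,
                    "ischemia_h": m.ischemia_h,
                    "reperfusion_h": m.reperfusion_h,
                    "replicate": m.replicate,
                    "label": lab,
                }
            )
        return pd.DataFrame(rows)

    def phase_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.spectra:
            out[s.meta.phase] = out.get(s.meta.phase, 0) + 1
        return out
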