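"""Tidy long-format container for longitudinal biomarker measurements."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ARMS", "SAMPLE_COLUMNS", "PATIENT_COLUMNS", "LongitudinalDataset"]

ARMS = ("standard", "experimental")

SAMPLE_COLUMNS = [
    "patient_id",
    "arm",
    "biomarker",
    "time_days",
    "concentration",
    "visit_label",
    "is_progression_sample",
]

PATIENT_COLUMNS = ["patient_id", "arm", "pfs_days", "progressed"]


@dataclass
class LongitudinalDataset:
    """Timed biomarker measurements plus per-patient outcome metadata.

    ``samples`` holds one row per (patient, biomarker, time) measurement with
    columns :data:`SAMPLE_COLUMNS`; negative ``time_days`` marks pre-treatment
    samples.  ``patients`` holds one row per patient with columns
    :data:`PATIENT_COLUMNS`, where ``pfs_days`` is the progression-free
    interval (time of progression for progressed patients, censoring time
    otherwise).
    """

    samples: pd.DataFrame
    patients: pd.DataFrame
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate:
            self._validate()

    # -- validation -----------------------------------------------------
    def _validate(self) -> None:
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing required column {col!r}")
        for col in PATIENT_COLUMNS:
            if col not in self.patients.columns:
                raise ValueError(f"patients table missing required column {col!r}")
        s = self.samples
        if len(s) == 0:
            raise ValueError("dataset contains no samples")
        bad_arm = set(s["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise ValueError(f"unknown treatment arm label(s): {sorted(bad_arm)}")
        if (s["concentration"] <= 0).any():
            raise ValueError("all concentrations must be strictly positive")
        dup = s.duplicated(subset=["patient_id", "biomarker", "time_days"])
        if dup.any():
            first = s.loc[dup.idxmax()]
            raise ValueError(
                "duplicate measurement for patient "
                f"{first['patient_id']!r}, biomarker {first['biomarker']!r}, "
                f"time {first['time_days']}"
            )
        if (self.patients["pfs_days"] <= 0).any():
            raise ValueError("pfs_days must be positive")
        grouped = s.groupby(["patient_id", "biomarker"], sort=False)
        if not grouped["time_days"].apply(lambda t: t.is_monotonic_increasing).all():
            # groupby preserves row order; generator and readers sort first
            raise ValueError("times within a patient-biomarker series must increase")
        if (grouped["is_progression_sample"].sum() > 1).any():
            raise ValueError("at most one progression sample per patient-biomarker")
        has_pre = grouped["time_days"].min() < 0
        if not has_pre.all():
            missing = has_pre[~has_pre].index[0]
            raise ValueError(
                f"patient {missing[0]!r} has no pre-treatment sample for "
                f"biomarker {missing[1]!r}"
            )
        unknown = set(s["patient_id"]) - set(self.patients["patient_id"])
        if unknown:
            raise ValueError(f"samples reference unknown patients: {sorted(unknown)[:5]}")

    # -- convenience accessors ------------------------------------------
    @property
    def biomarkers(self) -> list[str]:
        return sorted(self.samples["biomarker"].unique())

    def arm_of(self, patient_id: str) -> str:
        row = self.patients.loc[self.patients["patient_id"] == patient_id]
        if row.empty:
            raise KeyError(f"unknown patient {patient_id!r}")
        return str(row["arm"].iloc[0])

    def patient_series(self, patient_id: str, biomarker: str) -> pd.DataFrame:
        """All measurements of one biomarker for one patient, time-ordered."""
        mask = (self.samples["patient_id"] == patient_id) & (
            self.samples["biomarker"] == biomarker
        )
        return self.samples.loc[mask].sort_values("time_days").reset_index(drop=True)

    def summary(self) -> str:
        n_by_arm = self.patients.groupby("arm")["patient_id"].nunique().to_dict()
        per_patient = self.samples.groupby(["patient_id", "biomarker"]).size()
        return (
            f"{len(self.patients)} patients ({n_by_arm}), "
            f"{len(self.samples)} measurements of {len(self.biomarkers)} biomarker(s), "
            f"{per_patient.mean():.1f} samples per patient-biomarker"
        )

    def with_composite(self, name: str = "Ang1xTie2", tie2: str = "Tie2",
                       ang1: str = "Ang1") -> "LongitudinalDataset":
        """Return a dataset extended with the Tie2 x log2(Ang1) composite.

        Only visits where both components were measured contribute rows.
        """
        from .trajectory import composite_ang1_tie2

        s = self.samples
        tie2_rows = s[s["biomarker"] == tie2]
        ang1_rows = s[s["biomarker"] == ang1]
        merged = tie2_rows.merge(
            ang1_rows[["patient_id", "time_days", "concentration"]],
            on=["patient_id", "time_days"],
            suffixes=("", "_ang1"),
        )
        if merged.empty:
            raise ValueError(f"no time-matched {tie2}/{ang1} pairs in dataset")
        comp = merged.copy()
        comp["biomarker"] = name
        comp["concentration"] = composite_ang1_tie2(
            merged["concentration"].to_numpy(), merged["concentration_ang1"].to_numpy()
        )
        comp = comp[SAMPLE_COLUMNS]
        if (comp["concentration"] <= 0).any():
            raise ValueError(
                "composite produced non-positive values; "
                f"{ang1} concentrations at or below 1 are not supported"
            )
        samples = pd.concat([s, comp], ignore_index=True)
        samples = samples.sort_values(
            ["patient_id", "biomarker", "time_days"], kind="stable"
        ).reset_index(drop=True)
        return LongitudinalDataset(samples, self.patients.copy())

    def __eq__(self, other: object) -> bool:  # value equality for round-trips
        if not isinstance(other, LongitudinalDataset):
            return NotImplemented
        return self.samples.equals(other.samples) and self.patients.equals(other.patients)
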