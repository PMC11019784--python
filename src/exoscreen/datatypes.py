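"""Core tabular containers for the supplementation-screen pipeline.

Every container is a thin dataclass around one or more pandas DataFrames
with schema validation at construction time.  The pipeline stages pass
these objects around in memory; :mod:`exoscreen.io` maps each of them to
a TSV file format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError

CONTROL_METABOLITE = ""  # sentinel for the unsupplemented control row

SAMPLE_CLASSES = ("supernatant_day10", "background_medium", "supplemented_reference")


@dataclass(frozen=True)
class ExperimentDesign:
    """Enumerated culture conditions: supplement x concentration plus control.

    ``frame`` columns:

    condition_id : str, unique
    metabolite_id : str, empty string for the control row
    concentration_uM : float, NaN for control
    n_replicates : int
    unmeasurable : bool — supplement cannot be seen by the MS method and is
        excluded from consumption analysis (e.g. too small / not ionizing
        in negative mode).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        required = ["condition_id", "metabolite_id", "concentration_uM",
                    "n_replicates", "unmeasurable"]
        for col in required:
            if col not in f.columns:
                raise DesignError(f"missing design column {col!r}", field=col)
        if f["condition_id"].duplicated().any():
            dup = f.loc[f["condition_id"].duplicated(), "condition_id"].iloc[0]
            raise DesignError(f"duplicate condition_id {dup!r}", field="condition_id")
        is_control = f["metabolite_id"] == CONTROL_METABOLITE
        if is_control.sum() != 1:
            raise DesignError(
                f"expected exactly one control row, found {int(is_control.sum())}",
                field="metabolite_id")
        supp = f.loc[~is_control]
        pairs = supp[["metabolite_id", "concentration_uM"]]
        if pairs.duplicated().any():
            raise DesignError("duplicate (metabolite, concentration) pair",
                              field="metabolite_id")
        if (supp["concentration_uM"] <= 0).any():
            raise DesignError("concentration_uM must be positive",
                              field="concentration_uM")
        if (f["n_replicates"] < 1).any():
            raise DesignError("n_replicates must be >= 1", field="n_replicates")

    @property
    def control_id(self) -> str:
        mask = self.frame["metabolite_id"] == CONTROL_METABOLITE
        return str(self.frame.loc[mask, "condition_id"].iloc[0])

    @property
    def condition_ids(self) -> list[str]:
        return list(self.frame["condition_id"])

    @property
    def supplemented(self) -> pd.DataFrame:
        """Rows for supplemented conditions only (control excluded)."""
        return self.frame.loc[self.frame["metabolite_id"] != CONTROL_METABOLITE]

    @property
    def n_conditions(self) -> int:
        return len(self.frame)

    def measurable_metabolites(self) -> list[str]:
        """Supplemented metabolites eligible for consumption analysis."""
        supp = self.supplemented
        ok = supp.loc[~supp["unmeasurable"].astype(bool), "metabolite_id"]
        return sorted(set(ok))

    def supplement_of(self, condition_id: str) -> str:
        """Metabolite supplemented in a condition ('' for the control)."""
        row = self.frame.loc[self.frame["condition_id"] == condition_id]
        if row.empty:
            raise DesignError(f"unknown condition {condition_id!r}")
        return str(row["metabolite_id"].iloc[0])


@dataclass(frozen=True)
class GrowthCurves:
    """Long-format OD750 time series.

    ``frame`` columns: condition_id, replicate (int), day (float), od750 (float).
    Times must be strictly ascending within each (condition, replicate).
    """

    frame: pd.DataFrame

    def __post_init__(self):
        f = self.frame
        for col in ("condition_id", "replicate", "day", "od750"):
            if col not in f.columns:
                raise ValidationError(f"missing growth column {col!r}", field=col)
        if (f["od750"] < 0).any():
            raise ValidationError("od750 must be nonnegative", field="od750")
        grouped = f.groupby(["condition_id", "replicate"])["day"]
        if not grouped.apply(lambda d: bool(np.all(np.diff(d.to_numpy()) > 0))).all():
            raise ValidationError("days must be strictly ascending per replicate",
                                  field="day")


@dataclass(frozen=True)
class FeatureMatrix:
    """Ion x sample intensity matrix with sample metadata.

    intensities : DataFrame, index ion_id, columns sample_id, nonnegative floats
        (absent measurements are explicit zeros, never NaN).
    ions : DataFrame with columns ion_id, mz (Da, positive), polarity.
    samples : DataFrame with columns sample_id, condition_id ('' for
        background medium), replicate, sample_class in
        {supernatant_day10, background_medium, supplemented_reference}.
    """

    intensities: pd.DataFrame
    ions: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if len(self.intensities.index) == 0:
            raise ValidationError("no ions in feature matrix")
        if self.intensities.isna().any().any():
            raise ValidationError("missing intensity cells are not allowed")
        if (self.intensities.to_numpy() < 0).any():
            raise ValidationError("negative intensity", field="intensity")
        if list(self.intensities.columns) != list(self.samples["sample_id"]):
            raise ValidationError(
                "matrix columns do not match sample metadata rows")
        if list(self.intensities.index) != list(self.ions["ion_id"]):
            raise ValidationError("matrix rows do not match ion metadata rows")
        if (self.ions["mz"] <= 0).any():
            raise ValidationError("mz must be positive", field="mz")
        bad = ~self.samples["sample_class"].isin(SAMPLE_CLASSES)
        if bad.any():
            raise ValidationError(
                f"unknown sample_class {self.samples.loc[bad, 'sample_class'].iloc[0]!r}",
                field="sample_class")
        if (self.samples["sample_class"] == "background_medium").sum() < 1:
            raise ValidationError("at least one background_medium sample required")

    def sample_ids(self, sample_class: str, condition_id: str | None = None) -> list[str]:
        s = self.samples
        mask = s["sample_class"] == sample_class
        if condition_id is not None:
            mask &= s["condition_id"] == condition_id
        return list(s.loc[mask, "sample_id"])

    @property
    def n_ions(self) -> int:
        return len(self.intensities.index)


@dataclass(frozen=True)
class MassTable:
    """Metabolite -> monoisotopic neutral mass (Da)."""

    frame: pd.DataFrame  # columns: metabolite_id, monoisotopic_mass_da

    def __post_init__(self):
        f = self.frame
        for col in ("metabolite_id", "monoisotopic_mass_da"):
            if col not in f.columns:
                raise ValidationError(f"missing mass column {col!r}", field=col)
        if f["metabolite_id"].duplicated().any():
            raise ValidationError("duplicate metabolite_id in mass table",
                                  field="metabolite_id")
        if (f["monoisotopic_mass_da"] <= 0).any():
            raise ValidationError("masses must be positive",
                                  field="monoisotopic_mass_da")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.frame["metabolite_id"])

    def mass_of(self, metabolite_id: str) -> float:
        row = self.frame.loc[self.frame["metabolite_id"] == metabolite_id]
        if row.empty:
            raise ValidationError(f"metabolite {metabolite_id!r} not in mass table")
        return float(row["monoisotopic_mass_da"].iloc[0])


@dataclass(frozen=True)
class PathwayDB:
    """Many-to-many metabolite -> pathway membership."""

    frame: pd.DataFrame  # columns: metabolite_id, pathway_id

    def __post_init__(self):
        f = self.frame
        for col in ("metabolite_id", "pathway_id"):
            if col not in f.columns:
                raise ValidationError(f"missing pathway column {col!r}", field=col)
        if f.duplicated().any():
            raise ValidationError("duplicate (metabolite, pathway) row")

    def pathways_of(self, metabolite_id: str) -> set[str]:
        f = self.frame
        return set(f.loc[f["metabolite_id"] == metabolite_id, "pathway_id"])

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(set(self.frame["pathway_id"]))


@dataclass(frozen=True)
class NormalizedExometabolome:
    """Metabolite x condition matrix of 0-1 normalized exudation intensities.

    values : DataFrame, index metabolite_id, columns condition_id, in [0, 1].
    flags : same-shape DataFrame of provenance strings in
        {measured, below_lod_reassigned, supplement_masked}.
    """

    values: pd.DataFrame
    flags: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.size and ((v < -1e-12).any() or (v > 1 + 1e-12).any()):
            raise ValidationError("normalized values must lie in [0, 1]")
        if self.flags is not None and self.flags.shape != self.values.shape:
            raise ValidationError("flags shape does not match values shape")
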