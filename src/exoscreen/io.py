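"""TSV reading and writing for every pipeline artifact.

All formats are tab-separated UTF-8 with a single header row.  The
feature matrix is wide (ions as rows, samples as columns) with a sidecar
sample-metadata table.  Readers validate strictly and raise
:class:`~exoscreen.errors.ValidationError` naming file, row and field
rather than silently coercing; ``write(read(f))`` followed by ``read``
is the identity for every format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    CONTROL_METABOLITE,
    ExperimentDesign,
    FeatureMatrix,
    GrowthCurves,
    MassTable,
    NormalizedExometabolome,
    PathwayDB,
)
from .errors import ValidationError


def _read_tsv(path, required_columns):
    path = Path(path)
    if not path.exists():
        raise ValidationError("file not found", file=str(path))
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # malformed TSV
        raise ValidationError(f"cannot parse TSV: {exc}", file=str(path)) from exc
    for col in required_columns:
        if col not in frame.columns:
            raise ValidationError("missing column", file=str(path), field=col)
    return frame


def _numeric(frame, col, path, allow_empty=False):
    """Convert a string column to float, reporting the first bad row (1-based
    data rows, header not counted)."""
    raw = frame[col]
    empty = raw == ""
    vals = pd.to_numeric(raw.mask(empty), errors="coerce")
    bad = vals.isna() & ~empty
    if bad.any():
        rownum = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValidationError(f"malformed number {raw[bad].iloc[0]!r}",
                              file=str(path), row=rownum, field=col)
    if not allow_empty and empty.any():
        rownum = int(np.flatnonzero(empty.to_numpy())[0]) + 1
        raise ValidationError("empty numeric cell", file=str(path),
                              row=rownum, field=col)
    return vals


# ---------------------------------------------------------------- design

def read_design(path) -> ExperimentDesign:
    f = _read_tsv(path, ["condition_id", "metabolite_id", "concentration_uM",
                         "n_replicates"])
    conc = _numeric(f, "concentration_uM", path, allow_empty=True)
    reps = _numeric(f, "n_replicates", path)
    unmeasurable = (f["unmeasurable"].isin(("1", "true", "True"))
                    if "unmeasurable" in f.columns
                    else pd.Series(False, index=f.index))
    out = pd.DataFrame({
        "condition_id": f["condition_id"],
        "metabolite_id": f["metabolite_id"],
        "concentration_uM": conc,
        "n_replicates": reps.astype(int),
        "unmeasurable": unmeasurable.astype(bool),
    })
    try:
        return ExperimentDesign(out)
    except ValidationError as exc:
        raise type(exc)(str(exc), file=str(path)) from exc


def write_design(design: ExperimentDesign, path) -> None:
    f = design.frame.copy()
    f["concentration_uM"] = [
        "" if pd.isna(c) else (str(int(c)) if float(c).is_integer() else repr(float(c)))
        for c in f["concentration_uM"]]
    f["unmeasurable"] = f["unmeasurable"].astype(bool).astype(int)
    f.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- growth

def read_growth(path) -> GrowthCurves:
    f = _read_tsv(path, ["condition_id", "replicate", "day", "od750"])
    out = pd.DataFrame({
        "condition_id": f["condition_id"],
        "replicate": _numeric(f, "replicate", path).astype(int),
        "day": _numeric(f, "day", path),
        "od750": _numeric(f, "od750", path),
    })
    try:
        return GrowthCurves(out)
    except ValidationError as exc:
        raise type(exc)(str(exc), file=str(path)) from exc


def write_growth(curves: GrowthCurves, path) -> None:
    f = curves.frame.copy()
    f.to_csv(path, sep="\t", index=False, float_format="%.10g")


# -------------------------------------------------------- feature matrix

def read_feature_matrix(path_matrix, path_samples) -> FeatureMatrix:
    m = _read_tsv(path_matrix, ["ion_id", "mz", "polarity"])
    s = _read_tsv(path_samples, ["sample_id", "condition_id", "replicate",
                                 "sample_class"])
    sample_cols = [c for c in m.columns if c not in ("ion_id", "mz", "polarity")]
    if not sample_cols:
        raise ValidationError("no ions or no sample columns",
                              file=str(path_matrix))
    if sample_cols != list(s["sample_id"]):
        raise ValidationError(
            "matrix sample columns do not match sample metadata rows",
            file=str(path_samples), field="sample_id")
    intens = pd.DataFrame(
        {c: _numeric(m, c, path_matrix).to_numpy() for c in sample_cols},
        index=pd.Index(m["ion_id"], name="ion_id"), dtype=float)
    if (intens.to_numpy() < 0).any():
        raise ValidationError("negative intensity", file=str(path_matrix),
                              field="intensity")
    ions = pd.DataFrame({"ion_id": m["ion_id"],
                         "mz": _numeric(m, "mz", path_matrix),
                         "polarity": m["polarity"]})
    samples = pd.DataFrame({
        "sample_id": s["sample_id"],
        "condition_id": s["condition_id"],
        "replicate": _numeric(s, "replicate", path_samples, allow_empty=True)
        .fillna(0).astype(int),
        "sample_class": s["sample_class"],
    })
    try:
        return FeatureMatrix(intens, ions, samples)
    except ValidationError as exc:
        raise type(exc)(str(exc), file=str(path_matrix)) from exc


def write_feature_matrix(fm: FeatureMatrix, path_matrix, path_samples) -> None:
    wide = pd.concat([fm.ions.reset_index(drop=True),
                      fm.intensities.reset_index(drop=True)], axis=1)
    wide.to_csv(path_matrix, sep="\t", index=False, float_format="%.10g")
    fm.samples.to_csv(path_samples, sep="\t", index=False)


# --------------------------------------------------------------- masses

def read_masses(path) -> MassTable:
    f = _read_tsv(path, ["metabolite_id", "monoisotopic_mass_da"])
    out = pd.DataFrame({
        "metabolite_id": f["metabolite_id"],
        "monoisotopic_mass_da": _numeric(f, "monoisotopic_mass_da", path),
    })
    try:
        return MassTable(out)
    except ValidationError as exc:
        raise type(exc)(str(exc), file=str(path)) from exc


def write_masses(masses: MassTable, path) -> None:
    masses.frame.to_csv(path, sep="\t", index=False, float_format="%.8f")


# -------------------------------------------------------------- pathways

def read_pathways(path) -> PathwayDB:
    f = _read_tsv(path, ["metabolite_id", "pathway_id"])
    try:
        return PathwayDB(f[["metabolite_id", "pathway_id"]].copy())
    except ValidationError as exc:
        raise type(exc)(str(exc), file=str(path)) from exc


def write_pathways(db: PathwayDB, path) -> None:
    db.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------- normalized exometabolome

def read_normalized(path_values, path_flags=None) -> NormalizedExometabolome:
    v = _read_tsv(path_values, ["metabolite_id"])
    conds = [c for c in v.columns if c != "metabolite_id"]
    values = pd.DataFrame(
        {c: _numeric(v, c, path_values).to_numpy() for c in conds},
        index=pd.Index(v["metabolite_id"], name="metabolite_id"), dtype=float)
    flags = None
    if path_flags is not None:
        fl = _read_tsv(path_flags, ["metabolite_id"])
        flags = fl.set_index("metabolite_id")[conds]
    return NormalizedExometabolome(values, flags)


def write_normalized(norm: NormalizedExometabolome, path_values,
                     path_flags=None) -> None:
    norm.values.rename_axis("metabolite_id").reset_index().to_csv(
        path_values, sep="\t", index=False, float_format="%.12g")
    if path_flags is not None and norm.flags is not None:
        norm.flags.rename_axis("metabolite_id").reset_index().to_csv(
            path_flags, sep="\t", index=False)
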