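"""Specimen measurement tables and the three-property feature space.

Each veneer disc is characterised by three physical properties:

* dry weight (g), measured after oven drying;
* moisture absorption (% of dry weight) after reconditioning at fixed
  humidity, ``(wet - dry) / dry * 100``;
* mode skewness of the reflected-light intensity distribution
  (dimensionless; see :mod:`veneermatch.image_brightness`).

This module reads and validates specimen tables, computes moisture
absorption from raw weights, and assembles the N x 3 feature matrix
consumed by the clustering stage. The column order is fixed
(dry weight, moisture %, mode skewness) so that partitions are
reproducible across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDataError,
    EvaporativeLossWarning,
    LoadError,
    MeasurementError,
)

#: Fixed feature-column order used throughout the pipeline.
FEATURE_COLUMNS = ("dry_weight_g", "moisture_pct", "mode_skewness")


@dataclass
class Specimen:
    """One veneer disc with its source-sheet label and measured properties.

    ``sheet_id`` records the veneer sheet the disc was punched from; it is
    the ground-truth provenance label used downstream to assess how well
    clustering recovers the source of origin.
    """

    specimen_id: str
    sheet_id: str
    dry_weight: float
    moisture_absorption: float
    mode_skewness: float
    wet_weight: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.dry_weight) or self.dry_weight <= 0:
            raise MeasurementError(
                f"specimen {self.specimen_id!r}: dry weight must be positive "
                f"and finite, got {self.dry_weight!r}"
            )
        if not np.isfinite(self.moisture_absorption) or self.moisture_absorption < 0:
            raise MeasurementError(
                f"specimen {self.specimen_id!r}: moisture absorption must be "
                f"non-negative and finite, got {self.moisture_absorption!r}"
            )
        if not np.isfinite(self.mode_skewness):
            raise MeasurementError(
                f"specimen {self.specimen_id!r}: mode skewness must be finite"
            )

    @property
    def features(self) -> np.ndarray:
        """The specimen's coordinates in the fixed 3-D property space."""
        return np.array(
            [self.dry_weight, self.moisture_absorption, self.mode_skewness]
        )


@dataclass
class FeatureMatrix:
    """N x 3 property matrix with its specimen ordering and scaling record.

    ``center``/``scale`` are per-column and are ``None`` when the matrix
    holds raw values. Standardized columns have mean 0 and unit
    (population) standard deviation.
    """

    values: np.ndarray
    specimen_order: list[str]
    sheet_ids: list[str] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_COLUMNS):
            raise MeasurementError(
                f"feature matrix must be N x {len(FEATURE_COLUMNS)}, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[0] != len(self.specimen_order):
            raise MeasurementError("row count does not match specimen_order length")
        if not np.all(np.isfinite(self.values)):
            raise MeasurementError("feature matrix contains non-finite values")

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    def sheet_map(self) -> dict[str, str]:
        """Mapping from specimen id to its source-sheet label."""
        return dict(zip(self.specimen_order, self.sheet_ids))

    def row_of(self, specimen_id: str) -> int:
        return self.specimen_order.index(specimen_id)


def moisture_absorption(wet_weight: float, dry_weight: float) -> float:
    """Moisture uptake as a percentage of dry weight.

    Parameters
    ----------
    wet_weight, dry_weight
        Masses in grams of the same specimen after humid reconditioning
        and after oven drying, respectively.

    Returns
    -------
    float
        ``(wet_weight - dry_weight) / dry_weight * 100``.

    Raises
    ------
    MeasurementError
        If ``dry_weight`` is not strictly positive.

    Warns
    -----
    EvaporativeLossWarning
        When ``wet_weight < dry_weight``; the (negative) value is still
        returned so the caller can decide whether to discard the record.
    """
    if not np.isfinite(dry_weight) or dry_weight <= 0:
        raise MeasurementError(f"dry weight must be positive, got {dry_weight!r}")
    if wet_weight < dry_weight:
        warnings.warn(
            f"wet weight {wet_weight} g below dry weight {dry_weight} g",
            EvaporativeLossWarning,
            stacklevel=2,
        )
    return (wet_weight - dry_weight) / dry_weight * 100.0


def load_specimens(path: str | Path, cutoff: int = 60) -> list[Specimen]:
    """Read a specimen table (CSV) into validated :class:`Specimen` records.

    Required columns: ``specimen_id``, ``sheet_id``, ``dry_weight_g`` and
    either ``moisture_pct`` or ``wet_weight_g``, and either
    ``mode_skewness`` or ``image_path``. Moisture is computed from the
    weights when only ``wet_weight_g`` is given; mode skewness is computed
    from the photograph when only ``image_path`` is given (``cutoff`` is
    the background intensity threshold passed to the image module;
    relative image paths are resolved against the table's directory).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"specimen table not found: {path}")
    try:
        table = pd.read_csv(path, dtype={"specimen_id": str, "sheet_id": str})
    except Exception as exc:  # noqa: BLE001 - surface any parse failure uniformly
        raise LoadError(f"cannot parse {path}: {exc}") from exc

    for col in ("specimen_id", "sheet_id", "dry_weight_g"):
        if col not in table.columns:
            raise LoadError(f"{path}: missing mandatory column {col!r}")
    has_moisture = "moisture_pct" in table.columns
    has_wet = "wet_weight_g" in table.columns
    if not (has_moisture or has_wet):
        raise LoadError(f"{path}: need column 'moisture_pct' or 'wet_weight_g'")
    has_skew = "mode_skewness" in table.columns
    has_image = "image_path" in table.columns
    if not (has_skew or has_image):
        raise LoadError(f"{path}: need column 'mode_skewness' or 'image_path'")

    dup = table["specimen_id"][table["specimen_id"].duplicated()]
    if len(dup):
        raise LoadError(f"{path}: duplicated specimen_id {dup.iloc[0]!r}")

    def _num(row_idx, row, col, required=True):
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            if required:
                raise LoadError(f"{path}: row {row_idx + 2}: missing value in {col!r}")
            return None
        try:
            return float(raw)
        except (TypeError, ValueError) as exc:
            raise LoadError(
                f"{path}: row {row_idx + 2}: unparseable number {raw!r} in {col!r}"
            ) from exc

    specimens = []
    for idx, row in table.iterrows():
        dry = _num(idx, row, "dry_weight_g")
        wet = _num(idx, row, "wet_weight_g", required=False) if has_wet else None
        if has_moisture and row.get("moisture_pct") == row.get("moisture_pct"):
            moist = _num(idx, row, "moisture_pct")
        else:
            if wet is None:
                raise LoadError(
                    f"{path}: row {idx + 2}: neither moisture_pct nor wet_weight_g"
                )
            if dry is None or dry <= 0:
                raise LoadError(
                    f"{path}: row {idx + 2}: dry weight must be positive"
                )
            moist = moisture_absorption(wet, dry)
        if has_skew and row.get("mode_skewness") == row.get("mode_skewness"):
            skew = _num(idx, row, "mode_skewness")
        else:
            image = row.get("image_path")
            if not isinstance(image, str) or not image:
                raise LoadError(
                    f"{path}: row {idx + 2}: neither mode_skewness nor image_path"
                )
            from .image_brightness import mode_skewness_from_file

            image_file = Path(image)
            if not image_file.is_absolute():
                image_file = path.parent / image_file
            skew = mode_skewness_from_file(image_file, cutoff=cutoff)["mode_skewness"]
        try:
            specimens.append(
                Specimen(
                    specimen_id=str(row["specimen_id"]),
                    sheet_id=str(row["sheet_id"]),
                    dry_weight=dry,
                    wet_weight=wet,
                    moisture_absorption=moist,
                    mode_skewness=skew,
                )
            )
        except MeasurementError as exc:
            raise LoadError(f"{path}: row {idx + 2}: {exc}") from exc
    return specimens


def write_specimens(specimens: list[Specimen], path: str | Path) -> None:
    """Write specimens back to the CSV schema ``load_specimens`` reads."""
    frame = pd.DataFrame(
        {
            "specimen_id": [s.specimen_id for s in specimens],
            "sheet_id": [s.sheet_id for s in specimens],
            "dry_weight_g": [s.dry_weight for s in specimens],
            "wet_weight_g": [s.wet_weight for s in specimens],
            "moisture_pct": [s.moisture_absorption for s in specimens],
            "mode_skewness": [s.mode_skewness for s in specimens],
        }
    )
    frame.to_csv(path, index=False)


def build_feature_matrix(
    specimens: list[Specimen], standardize: bool = True
) -> FeatureMatrix:
    """Assemble the N x 3 feature matrix in the fixed column order.

    The three properties live on incommensurate scales (g, %,
    dimensionless) and clustering uses an unweighted Euclidean distance,
    so ``standardize`` defaults to on: each column is z-scored to mean 0
    and unit (population) standard deviation. Raw mode is retained for
    callers who want distances in the original units.
    """
    if len(specimens) < 2:
        raise MeasurementError("need at least 2 specimens to build a feature matrix")
    values = np.array([s.features for s in specimens], dtype=float)
    center = scale = None
    if standardize:
        center = values.mean(axis=0)
        scale = values.std(axis=0)
        for j, col in enumerate(FEATURE_COLUMNS):
            if scale[j] == 0:
                raise DegenerateDataError(
                    f"column {col!r} has zero variance; cannot standardize"
                )
        values = (values - center) / scale
    return FeatureMatrix(
        values=values,
        specimen_order=[s.specimen_id for s in specimens],
        sheet_ids=[s.sheet_id for s in specimens],
        center=center,
        scale=scale,
    )
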