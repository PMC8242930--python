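"""Segment taxonomy, the bundled calibration table, and conversion of naive
convex-hull BSPs into predicted soft-tissue BSPs.

The bundled table holds one linear model per (segment, parameter) cell —
13 segment keys x 10 parameters = 130 models — on the published transform
scale: log10 for mass and the three moments of inertia, linear for
everything else. Appendicular models are fitted on left-side segments;
right-side predictions use mirrored models (intercept sign flipped for
cm_y, ixy, iyz, applied to sign-flipped inputs).
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, replace

from .mass_properties import BSPVector, PARAMETER_NAMES

__all__ = [
    "APPENDICULAR_SEGMENTS",
    "AXIAL_SEGMENTS",
    "SEGMENT_NAMES",
    "MIRRORED_PARAMETERS",
    "SegmentLabel",
    "CalibrationModel",
    "CalibrationTable",
    "ExtrapolationWarning",
    "load_bundled_table",
    "predict_parameter",
    "predict_segment",
    "mirror_model",
    "mirror_bsp",
]

APPENDICULAR_SEGMENTS = ("arm", "forearm", "hand", "thigh", "shank", "foot")
AXIAL_SEGMENTS = ("head", "neck", "torso", "tail1", "tail2", "tail3", "tail4")
SEGMENT_NAMES = APPENDICULAR_SEGMENTS + AXIAL_SEGMENTS

#: Parameters whose sign flips under left/right mirroring (reflection in y).
MIRRORED_PARAMETERS = ("cm_y", "ixy", "iyz")

LOG10_PARAMETERS = ("mass", "ixx", "iyy", "izz")

#: Body-mass span of the specimens behind the bundled table (kg); inputs
#: implying masses far outside this range trigger an extrapolation warning.
CALIBRATION_MASS_RANGE_KG = (0.02, 450.0)


class ExtrapolationWarning(UserWarning):
    """A hull value lies outside the calibration's fitted range."""


@dataclass(frozen=True)
class SegmentLabel:
    """A segment name plus its body side.

    Axial segments (head, neck, torso, tail1-4) have side "none";
    appendicular (limb) segments are "left" or "right".
    """

    name: str
    side: str = "none"

    def __post_init__(self):
        if self.name not in SEGMENT_NAMES:
            raise ValueError(f"unknown segment {self.name!r}; expected one of {SEGMENT_NAMES}")
        if self.is_axial:
            if self.side != "none":
                raise ValueError(f"axial segment {self.name!r} cannot have side {self.side!r}")
        elif self.side not in ("left", "right"):
            raise ValueError(
                f"appendicular segment {self.name!r} needs side left or right, got {self.side!r}"
            )

    @property
    def is_axial(self) -> bool:
        return self.name in AXIAL_SEGMENTS

    @property
    def segment_class(self) -> str:
        return "axial" if self.is_axial else "appendicular"

    @property
    def fit_key(self) -> str:
        """The table key this segment is fitted under (left limbs + axial)."""
        return self.name

    @classmethod
    def parse(cls, text: str) -> "SegmentLabel":
        """Parse CLI-style labels: 'left_thigh', 'right_arm', 'torso', 'tail2'."""
        text = text.strip().lower()
        for side in ("left", "right"):
            prefix = side + "_"
            if text.startswith(prefix):
                return cls(text[len(prefix):], side)
        return cls(text, "none")


def transform_name(parameter: str) -> str:
    return "log10" if parameter in LOG10_PARAMETERS else "linear"


@dataclass(frozen=True)
class CalibrationModel:
    """One linear conversion on the stated transform scale:
    soft = a + b * hull (both sides transformed when transform == 'log10')."""

    segment: str
    side: str
    parameter: str
    intercept: float
    slope: float
    transform: str
    intercept_ci: tuple[float, float] | None = None
    slope_ci: tuple[float, float] | None = None
    method: str = "OLS"
    n: int | None = None
    r2: float | None = None
    rmse: float | None = None

    def __post_init__(self):
        if self.parameter not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.transform not in ("log10", "linear"):
            raise ValueError(f"transform must be log10 or linear, got {self.transform!r}")


@dataclass
class CalibrationTable:
    """Map of (segment fit key, parameter) -> CalibrationModel."""

    models: dict[tuple[str, str], CalibrationModel] = field(default_factory=dict)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.models)

    def get(self, segment_key: str, parameter: str) -> CalibrationModel:
        try:
            return self.models[(segment_key, parameter)]
        except KeyError:
            raise KeyError(
                f"no calibration model for segment {segment_key!r}, parameter {parameter!r}"
            ) from None

    def add(self, model: CalibrationModel) -> None:
        self.models[(model.segment, model.parameter)] = model

    def segments(self) -> list[str]:
        return sorted({seg for seg, _ in self.models})

    def to_csv(self, path) -> None:
        fieldnames = [
            "segment", "side", "parameter", "transform", "intercept", "slope",
            "intercept_lo", "intercept_hi", "slope_lo", "slope_hi",
            "method", "n", "r2", "rmse",
        ]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fieldnames)
            writer.writeheader()
            for (seg, param) in sorted(self.models):
                m = self.models[(seg, param)]
                writer.writerow({
                    "segment": seg,
                    "side": m.side,
                    "parameter": param,
                    "transform": m.transform,
                    "intercept": repr(m.intercept),
                    "slope": repr(m.slope),
                    "intercept_lo": "" if m.intercept_ci is None else repr(m.intercept_ci[0]),
                    "intercept_hi": "" if m.intercept_ci is None else repr(m.intercept_ci[1]),
                    "slope_lo": "" if m.slope_ci is None else repr(m.slope_ci[0]),
                    "slope_hi": "" if m.slope_ci is None else repr(m.slope_ci[1]),
                    "method": m.method,
                    "n": "" if m.n is None else m.n,
                    "r2": "" if m.r2 is None else repr(m.r2),
                    "rmse": "" if m.rmse is None else repr(m.rmse),
                })

    @classmethod
    def from_csv(cls, path_or_file, provenance: str = "") -> "CalibrationTable":
        table = cls(provenance=provenance)
        if hasattr(path_or_file, "read"):
            rows = list(csv.DictReader(path_or_file))
        else:
            with open(path_or_file, newline="") as fh:
                rows = list(csv.DictReader(fh))
        for row in rows:
            def opt_pair(lo_key, hi_key):
                lo, hi = row.get(lo_key, ""), row.get(hi_key, "")
                if lo == "" or hi == "":
                    return None
                return (float(lo), float(hi))

            table.add(CalibrationModel(
                segment=row["segment"],
                side=row["side"],
                parameter=row["parameter"],
                intercept=float(row["intercept"]),
                slope=float(row["slope"]),
                transform=row["transform"],
                intercept_ci=opt_pair("intercept_lo", "intercept_hi"),
                slope_ci=opt_pair("slope_lo", "slope_hi"),
                method=row.get("method", "OLS") or "OLS",
                n=int(row["n"]) if row.get("n") else None,
                r2=float(row["r2"]) if row.get("r2") else None,
                rmse=float(row["rmse"]) if row.get("rmse") else None,
            ))
        return table


def load_bundled_table() -> CalibrationTable:
    """Load the packaged 130-model calibration table (published OLS
    coefficients with 95% CIs, transcribed as printed)."""
    resource = importlib.resources.files("hullbsp").joinpath("data/calibration_table.csv")
    with resource.open("r", newline="") as fh:
        table = CalibrationTable.from_csv(
            fh, provenance="bundled mammalian hull-to-soft-tissue calibration"
        )
    if len(table) != 130:
        raise RuntimeError(f"bundled table corrupt: expected 130 models, found {len(table)}")
    return table


def predict_parameter(hull_value: float, model: CalibrationModel) -> float:
    """Convert one naive hull parameter value to a predicted soft-tissue
    value, in SI units on the natural (untransformed) scale."""
    if model.transform == "log10":
        if hull_value <= 0:
            raise ValueError(
                f"{model.segment}/{model.parameter}: log10 model needs a positive "
                f"input, got {hull_value}"
            )
        return 10.0 ** (model.intercept + model.slope * math.log10(hull_value))
    return model.intercept + model.slope * hull_value


def mirror_model(model: CalibrationModel) -> CalibrationModel:
    """Right-side counterpart of a left-side model.

    For the sign-flipping parameters (cm_y, ixy, iyz) the intercept sign is
    reversed (the slope acts on sign-flipped inputs); other parameters are
    unchanged apart from the side label.
    """
    if model.side != "left":
        raise ValueError(
            f"mirror_model applies to left-side appendicular models, got side {model.side!r}"
        )
    if model.parameter in MIRRORED_PARAMETERS:
        ici = None if model.intercept_ci is None else (
            -model.intercept_ci[1], -model.intercept_ci[0]
        )
        return replace(model, intercept=-model.intercept, intercept_ci=ici, side="right")
    return replace(model, side="right")


def mirror_bsp(bsp: BSPVector) -> BSPVector:
    """Reflect a BSP vector in the x-z plane: cm_y, ixy, iyz change sign."""
    return replace(bsp, cm_y=-bsp.cm_y, ixy=-bsp.ixy, iyz=-bsp.iyz)


def _check_extrapolation(segment: SegmentLabel, hull_bsp: BSPVector) -> None:
    lo, hi = CALIBRATION_MASS_RANGE_KG
    if not (lo * 1e-4 <= hull_bsp.mass <= hi):
        warnings.warn(
            f"hull mass {hull_bsp.mass:.4g} kg for segment {segment.name!r} lies "
            f"outside the ~{lo}-{hi} kg body-mass span of the calibration data; "
            "predictions are extrapolated",
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_segment(
    hull_bsp: BSPVector,
    segment: SegmentLabel | str,
    table: CalibrationTable | None = None,
    zero_axial: bool = False,
) -> BSPVector:
    """Predict all 10 soft-tissue BSPs of a segment from its naive hull BSPs.

    Right-sided segments are predicted with mirrored models. With
    ``zero_axial``, cm_y, ixy and iyz of axial segments are forced to
    exactly zero after prediction (lateral symmetry assumption for MDA).
    Predictions assume the hull BSP was computed at the calibration's
    nominal density of 1000 kg m^-3; rescale the *prediction* for other
    densities.
    """
    if isinstance(segment, str):
        segment = SegmentLabel.parse(segment)
    if table is None:
        table = load_bundled_table()
    _check_extrapolation(segment, hull_bsp)

    mirrored = segment.side == "right"
    source = mirror_bsp(hull_bsp) if mirrored else hull_bsp

    values = {}
    for parameter in PARAMETER_NAMES:
        model = table.get(segment.fit_key, parameter)
        values[parameter] = predict_parameter(source.get(parameter), model)

    if mirrored:
        for parameter in MIRRORED_PARAMETERS:
            values[parameter] = -values[parameter]
    if zero_axial and segment.is_axial:
        for parameter in MIRRORED_PARAMETERS:
            values[parameter] = 0.0

    return BSPVector(density=hull_bsp.density, **values)
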