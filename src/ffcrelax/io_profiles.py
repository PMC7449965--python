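"""Data model and tabular I/O for ¹H relaxation dispersion profiles.

A dispersion profile is one tissue sample's spin–lattice relaxation rate
R₁ measured as a function of proton Larmor frequency ν_H.  Frequencies are
exchanged in Hz (linear frequency); angular frequencies ω = 2πν are an
internal concern of the relaxation model.

Profiles are stored on disk as long-format, comma-delimited UTF-8 tables
with one row per (sample, field) point and a required header::

    sample_id,freq_hz,r1_s,r1_err_s[,patient_code,tissue_class,...]

Numbers are written with 17 significant digits so that a write→read
round-trip reproduces every float bit-exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TISSUE_CLASSES",
    "SARCOMA_GROUPS",
    "MUSCLE_GROUPS",
    "SampleMetadata",
    "DispersionProfile",
    "ProfileFormatError",
    "ProfileValidationError",
    "read_profiles",
    "write_profiles",
]

TISSUE_CLASSES = (
    "tumour",
    "muscle",
    "adjacent_muscle",
    "fat",
    "adjacent_fat",
    "lymph_node",
    "bone_marrow",
    "other",
)

#: Dispersion-shape groups: sarcomas are labelled A–E from the shallowest to
#: the steepest low-field dispersion; muscle profiles fall into I–III.
SARCOMA_GROUPS = ("A", "B", "C", "D", "E")
MUSCLE_GROUPS = ("I", "II", "III")


class ProfileFormatError(ValueError):
    """A profile table violates the expected file layout (e.g. missing column)."""


class ProfileValidationError(ValueError):
    """A profile's values violate the physical invariants of the data model."""


@dataclass(frozen=True)
class SampleMetadata:
    """Histology-side annotations attached to one tissue sample.

    ``myxoid``/``necrotic``/``inflammation`` are the MC/necrosis/I covariates
    from the histopathology table; ``group_label`` is the manually assigned
    dispersion group (A–E for sarcoma, I–III for muscle tissue).
    """

    patient_code: str = ""
    tissue_class: str = "other"
    myxoid: bool = False
    necrotic: bool = False
    inflammation: bool = False
    group_label: str | None = None
    free_text: str | None = None

    def __post_init__(self) -> None:
        if self.tissue_class not in TISSUE_CLASSES:
            raise ProfileValidationError(
                f"unknown tissue_class {self.tissue_class!r}; "
                f"expected one of {TISSUE_CLASSES}"
            )
        if self.group_label is not None:
            if self.tissue_class == "tumour" and self.group_label not in SARCOMA_GROUPS:
                raise ProfileValidationError(
                    f"tumour group_label must be one of {SARCOMA_GROUPS}, "
                    f"got {self.group_label!r}"
                )
            if (
                self.tissue_class in ("muscle", "adjacent_muscle")
                and self.group_label not in MUSCLE_GROUPS
            ):
                raise ProfileValidationError(
                    f"muscle group_label must be one of {MUSCLE_GROUPS}, "
                    f"got {self.group_label!r}"
                )


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    a.setflags(write=False)
    return a


@dataclass(frozen=True)
class DispersionProfile:
    """One sample's R₁(ν_H) curve with one-sigma point errors.

    Invariants: frequencies strictly increasing and positive; R₁ positive;
    errors non-negative; equal lengths.  Instances are immutable — the
    scaling and fitting stages always return new profiles.
    """

    sample_id: str
    frequencies: np.ndarray
    r1: np.ndarray
    r1_err: np.ndarray
    metadata: SampleMetadata = field(default_factory=SampleMetadata)

    def __post_init__(self) -> None:
        object.__setattr__(self, "frequencies", _readonly(self.frequencies))
        object.__setattr__(self, "r1", _readonly(self.r1))
        object.__setattr__(self, "r1_err", _readonly(self.r1_err))
        f, r, e = self.frequencies, self.r1, self.r1_err
        if not (f.ndim == r.ndim == e.ndim == 1):
            raise ProfileValidationError(f"profile {self.sample_id}: arrays must be 1-D")
        if not (len(f) == len(r) == len(e)):
            raise ProfileValidationError(
                f"profile {self.sample_id}: lengths differ "
                f"({len(f)}, {len(r)}, {len(e)})"
            )
        if len(f) == 0:
            raise ProfileValidationError(f"profile {self.sample_id}: empty profile")
        if not np.all(f > 0):
            raise ProfileValidationError(
                f"profile {self.sample_id}: non-positive frequency"
            )
        if not np.all(np.diff(f) > 0):
            raise ProfileValidationError(
                f"profile {self.sample_id}: frequencies not strictly increasing"
            )
        if not np.all(r > 0):
            raise ProfileValidationError(f"profile {self.sample_id}: non-positive R1")
        if not np.all(e >= 0):
            raise ProfileValidationError(f"profile {self.sample_id}: negative R1 error")

    @property
    def n_points(self) -> int:
        return len(self.frequencies)

    def replace(self, **changes) -> "DispersionProfile":
        """Return a copy with the given fields replaced (validates anew)."""
        return dataclasses.replace(self, **changes)

    def __eq__(self, other) -> bool:  # value equality on all fields
        if not isinstance(other, DispersionProfile):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.frequencies, other.frequencies)
            and np.array_equal(self.r1, other.r1)
            and np.array_equal(self.r1_err, other.r1_err)
            and self.metadata == other.metadata
        )


_REQUIRED_COLUMNS = ("sample_id", "freq_hz", "r1_s", "r1_err_s")
_META_COLUMNS = (
    "patient_code",
    "tissue_class",
    "myxoid",
    "necrotic",
    "inflammation",
    "group_label",
    "free_text",
)
_BOOL_META = ("myxoid", "necrotic", "inflammation")


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    if pd.isna(v):
        return False
    return bool(v)


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return None
    s = str(v)
    return s if s != "" else None


def read_profiles(path: str | Path) -> list[DispersionProfile]:
    """Read a long-format profile table into a list of profiles.

    One :class:`DispersionProfile` per distinct ``sample_id``, points sorted
    by frequency.  Metadata columns are optional; duplicated
    (sample, frequency) rows raise a validation error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ProfileFormatError(f"{path}: missing required column {col!r}")
    profiles: list[DispersionProfile] = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("freq_hz", kind="stable")
        freqs = sub["freq_hz"].to_numpy(dtype=float)
        if np.any(np.diff(freqs) == 0):
            raise ProfileValidationError(
                f"{path}: duplicated (sample, frequency) rows for sample {sample_id}"
            )
        row0 = sub.iloc[0]
        meta_kwargs = {}
        for col in _META_COLUMNS:
            if col not in sub.columns:
                continue
            v = row0[col]
            if col in _BOOL_META:
                meta_kwargs[col] = _parse_bool(v)
            elif col in ("group_label", "free_text"):
                meta_kwargs[col] = _opt_str(v)
            else:
                meta_kwargs[col] = "" if pd.isna(v) else str(v)
        try:
            meta = SampleMetadata(**meta_kwargs)
            profiles.append(
                DispersionProfile(
                    sample_id=str(sample_id),
                    frequencies=freqs,
                    r1=sub["r1_s"].to_numpy(dtype=float),
                    r1_err=sub["r1_err_s"].to_numpy(dtype=float),
                    metadata=meta,
                )
            )
        except ProfileValidationError as exc:
            raise ProfileValidationError(f"{path}: {exc}") from exc
    return profiles


def write_profiles(profiles: Sequence[DispersionProfile], path: str | Path) -> None:
    """Write profiles as a long-format CSV (17 significant digits).

    An empty profile list produces a header-only file.  The inverse of
    :func:`read_profiles`: write→read→write is byte-identical.
    """
    path = Path(path)
    records = []
    for p in profiles:
        m = p.metadata
        for f, r, e in zip(p.frequencies, p.r1, p.r1_err):
            records.append(
                {
                    "sample_id": p.sample_id,
                    "freq_hz": f,
                    "r1_s": r,
                    "r1_err_s": e,
                    "patient_code": m.patient_code,
                    "tissue_class": m.tissue_class,
                    "myxoid": m.myxoid,
                    "necrotic": m.necrotic,
                    "inflammation": m.inflammation,
                    "group_label": "" if m.group_label is None else m.group_label,
                    "free_text": "" if m.free_text is None else m.free_text,
                }
            )
    columns = list(_REQUIRED_COLUMNS) + list(_META_COLUMNS)
    df = pd.DataFrame.from_records(records, columns=columns)
    df.to_csv(path, index=False, float_format="%.17g")
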