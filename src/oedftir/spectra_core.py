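"""Core data model and I/O for FTIR micro-spectroscopy cohorts.

The objects here mirror how infrared tissue-imaging studies organise their
data: a shared wavenumber grid (:class:`SpectralAxis`), single absorbance
spectra (:class:`Spectrum`), pixel-indexed hyperspectral tiles
(:class:`HyperspectralImage`), per-biopsy spectrum collections with a
clinical outcome label (:class:`LesionSample`), and a labelled cohort
(:class:`Cohort`).

Axes are stored ascending in cm^-1; conventional spectroscopy plots run
descending, which is handled at the plotting layer.  All spectra within a
cohort must share a single axis — cross-axis resampling is deliberately
unsupported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

__all__ = [
    "SpectralAxis",
    "Spectrum",
    "HyperspectralImage",
    "LesionSample",
    "Cohort",
    "make_axis",
    "read_cohort",
    "write_cohort",
    "image_to_spectra",
]

#: Valid clinical outcome labels: transforming / non-transforming.
OUTCOMES = ("T", "NT")

#: Default acquisition range and sampling interval, cm^-1.
DEFAULT_WN_MIN = 900.0
DEFAULT_WN_MAX = 3800.0
DEFAULT_WN_STEP = 4.0

#: Default tile geometry: 128 x 128 pixels, 5.5 um pixels (~0.5 mm^2 field).
DEFAULT_TILE_SHAPE = (128, 128)
DEFAULT_PIXEL_SIZE_UM = 5.5


@dataclass(frozen=True)
class SpectralAxis:
    """A uniformly spaced, strictly ascending wavenumber grid (cm^-1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("axis values must be a non-empty 1-D array")
        if vals.size > 1:
            steps = np.diff(vals)
            if np.any(steps <= 0):
                raise ValueError("axis values must be strictly increasing")
            # uniform spacing, except that gaps at integer multiples of the
            # base step are allowed (an axis with an excised window)
            base = steps.min()
            ratio = steps / base
            if not np.allclose(ratio, np.round(ratio), rtol=1e-6, atol=1e-6):
                raise ValueError("axis values must be uniformly spaced")

    @property
    def wn_min(self) -> float:
        return float(self.values[0])

    @property
    def wn_max(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        if self.values.size < 2:
            return 0.0
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=0, atol=1e-9
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, self.wn_min, self.wn_max))

    def index_range(self, lo: float, hi: float) -> np.ndarray:
        """Indices of grid points in the closed interval [lo, hi]."""
        return np.nonzero((self.values >= lo) & (self.values <= hi))[0]


def make_axis(
    wn_min: float = DEFAULT_WN_MIN,
    wn_max: float = DEFAULT_WN_MAX,
    step: float = DEFAULT_WN_STEP,
) -> SpectralAxis:
    """Build an ascending wavenumber grid from ``wn_min`` in steps of ``step``.

    The grid includes ``wn_min`` and every subsequent multiple of ``step``
    that does not exceed ``wn_max``.  The default 900–3800 cm^-1 at 4 cm^-1
    gives 726 points.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got step={step}")
    if wn_min >= wn_max:
        raise ValueError(
            f"wn_min must be below wn_max, got wn_min={wn_min}, wn_max={wn_max}"
        )
    # nudge by a relative epsilon so wn_max lands on the grid despite rounding
    n = int(np.floor((wn_max - wn_min) / step + 1e-9)) + 1
    return SpectralAxis(wn_min + step * np.arange(n))


@dataclass(frozen=True)
class Spectrum:
    """A single absorbance spectrum sampled on a :class:`SpectralAxis`."""

    axis: SpectralAxis
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=np.float64)
        object.__setattr__(self, "absorbance", a)
        if a.ndim != 1 or a.size != len(self.axis):
            raise ValueError(
                f"absorbance length {a.size} does not match axis length "
                f"{len(self.axis)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must all be finite")


@dataclass
class HyperspectralImage:
    """A pixel grid of absorbance spectra with an optional tissue mask.

    ``cube`` has shape ``(n_rows, n_cols, len(axis))``.  ``mask`` is a
    per-pixel integer label where 0 means background / non-tissue.
    """

    axis: SpectralAxis
    cube: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=np.float64)
        if self.cube.ndim != 3 or self.cube.shape[2] != len(self.axis):
            raise ValueError(
                f"cube shape {self.cube.shape} inconsistent with axis length "
                f"{len(self.axis)}"
            )
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=np.int64)
            if self.mask.shape != self.cube.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match pixel grid "
                    f"{self.cube.shape[:2]}"
                )

    @property
    def n_rows(self) -> int:
        return self.cube.shape[0]

    @property
    def n_cols(self) -> int:
        return self.cube.shape[1]


class LesionSample:
    """QC-passed dysplastic spectra of one biopsy plus its outcome label.

    Spectra are held as an ``(n_spectra, n_wavenumbers)`` matrix for
    efficiency; :attr:`spectra` exposes them as :class:`Spectrum` objects.
    ``meta`` carries free-form metadata (grade, site, synthetic ground
    truth).
    """

    def __init__(
        self,
        lesion_id: str,
        outcome: str,
        absorbance: np.ndarray,
        axis: SpectralAxis,
        meta: dict | None = None,
    ) -> None:
        if outcome not in OUTCOMES:
            raise ValueError(
                f"lesion {lesion_id!r}: outcome must be one of {OUTCOMES}, "
                f"got {outcome!r}"
            )
        a = np.asarray(absorbance, dtype=np.float64)
        if a.ndim != 2 or a.shape[1] != len(axis):
            raise ValueError(
                f"lesion {lesion_id!r}: absorbance shape {a.shape} does not "
                f"match axis length {len(axis)}"
            )
        if a.shape[0] < 1:
            raise ValueError(f"lesion {lesion_id!r}: at least 1 spectrum required")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"lesion {lesion_id!r}: non-finite absorbance")
        self.lesion_id = lesion_id
        self.outcome = outcome
        self.absorbance = a
        self.axis = axis
        self.meta: dict = dict(meta or {})

    @classmethod
    def from_spectra(
        cls,
        lesion_id: str,
        outcome: str,
        spectra: list[Spectrum],
        meta: dict | None = None,
    ) -> "LesionSample":
        if not spectra:
            raise ValueError(f"lesion {lesion_id!r}: at least 1 spectrum required")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis != axis:
                raise ValueError(f"lesion {lesion_id!r}: spectra use mixed axes")
        return cls(lesion_id, outcome, np.vstack([s.absorbance for s in spectra]), axis, meta)

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def spectra(self) -> list[Spectrum]:
        return [Spectrum(self.axis, row) for row in self.absorbance]

    def __repr__(self) -> str:
        return (
            f"LesionSample({self.lesion_id!r}, outcome={self.outcome!r}, "
            f"n_spectra={self.n_spectra})"
        )


@dataclass
class Cohort:
    """A labelled collection of lesion samples sharing one spectral axis."""

    samples: list[LesionSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.lesion_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate lesion_id {dup!r} in cohort")
        if self.samples:
            axis = self.samples[0].axis
            for s in self.samples[1:]:
                if s.axis != axis:
                    raise ValueError(
                        f"lesion {s.lesion_id!r} uses a different spectral axis "
                        "from the rest of the cohort"
                    )

    @property
    def axis(self) -> SpectralAxis:
        if not self.samples:
            raise ValueError("empty cohort has no axis")
        return self.samples[0].axis

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LesionSample]:
        return iter(self.samples)

    def __getitem__(self, lesion_id: str) -> LesionSample:
        for s in self.samples:
            if s.lesion_id == lesion_id:
                return s
        raise KeyError(lesion_id)

    def ids(self, outcome: str | None = None) -> list[str]:
        return [
            s.lesion_id for s in self.samples if outcome is None or s.outcome == outcome
        ]

    def require_both_classes(self) -> None:
        if not self.ids("T") or not self.ids("NT"):
            raise ValueError(
                "cohort must contain at least one T and one NT lesion for "
                "cross-validation"
            )


# ---------------------------------------------------------------------------
# Cohort I/O.  Manifest = JSON index {lesions: [{lesion_id, outcome, path}]}.
# Per-lesion spectra live either in an HDF5 container (datasets `axis`,
# `spectra`, optional `meta` JSON attribute) or delimited text whose first
# column is the wavenumber and remaining columns are spectra.
# ---------------------------------------------------------------------------


def _read_lesion_h5(path: Path) -> tuple[SpectralAxis, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        axis = SpectralAxis(f["axis"][...])
        key = "spectra" if "spectra" in f else "cube"
        data = f[key][...]
        if data.ndim == 3:  # stored as a cube: keep masked pixels (all if no mask)
            if "mask" in f:
                data = data[f["mask"][...] > 0]
            else:
                data = data.reshape(-1, data.shape[-1])
        meta = json.loads(f.attrs.get("meta", "{}"))
    return axis, data, meta


def _read_lesion_text(path: Path) -> tuple[SpectralAxis, np.ndarray, dict]:
    arr = np.loadtxt(path, delimiter=None, comments="#")
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] < 2:
        raise ValueError(f"{path}: delimited spectra file needs >=2 columns")
    return SpectralAxis(arr[:, 0]), arr[:, 1:].T.copy(), {}


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort manifest (JSON index) and its per-lesion spectra files."""
    path = Path(path)
    manifest = json.loads(path.read_text())
    samples: list[LesionSample] = []
    for rec in manifest.get("lesions", []):
        lesion_id = rec.get("lesion_id")
        if lesion_id is None:
            raise ValueError(f"{path}: manifest record without lesion_id: {rec}")
        outcome = rec.get("outcome")
        if outcome not in OUTCOMES:
            raise ValueError(
                f"{path}: lesion {lesion_id!r} has invalid outcome {outcome!r} "
                f"(must be one of {OUTCOMES})"
            )
        spath = path.parent / rec["path"]
        if spath.suffix in {".h5", ".hdf5"}:
            axis, data, meta = _read_lesion_h5(spath)
        else:
            axis, data, meta = _read_lesion_text(spath)
        meta.update(rec.get("meta", {}))
        samples.append(LesionSample(lesion_id, outcome, data, axis, meta))
    return Cohort(samples)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort as a JSON manifest plus one HDF5 file per lesion.

    Absorbances are stored at full 64-bit precision so a write/read
    round-trip is exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stem_dir = path.parent / (path.stem + "_data")
    stem_dir.mkdir(exist_ok=True)
    records = []
    for s in cohort:
        fname = stem_dir.name + f"/{s.lesion_id}.h5"
        with h5py.File(path.parent / fname, "w") as f:
            f.create_dataset("axis", data=s.axis.values)
            f.create_dataset("spectra", data=s.absorbance)
            f.attrs["meta"] = json.dumps(s.meta, default=_json_default)
        records.append({"lesion_id": s.lesion_id, "outcome": s.outcome, "path": fname})
    path.write_text(json.dumps({"lesions": records}, indent=1))
    return path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"cannot serialise {type(obj)}")


def image_to_spectra(
    img: HyperspectralImage, label: int
) -> list[tuple[tuple[int, int], Spectrum]]:
    """Extract the spectra of all pixels carrying a given mask label.

    Pixel coordinates are preserved so per-pixel predictions can be mapped
    back onto the tissue section later.
    """
    if img.mask is None:
        raise ValueError("image has no mask; cannot select pixels by label")
    rows, cols = np.nonzero(img.mask == label)
    return [
        ((int(r), int(c)), Spectrum(img.axis, img.cube[r, c]))
        for r, c in zip(rows, cols)
    ]
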