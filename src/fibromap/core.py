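"""Core containers: acquisition metadata, 4D signal stacks, parameter maps.

Units follow the conventions of small-animal imaging on a clinical 1.5 T
platform: b-values in s/mm^2 (diffusivities in mm^2/s), echo times in ms
(T2* in ms), repetition time and T1 in s, flip angles in degrees in metadata
and radians inside the maths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

# Default acquisition protocol (clinical-sequence derived, 1.5 T).
B_VALUES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 200.0, 400.0, 800.0)  # s/mm^2
UTE_ECHOES_MS = (0.07, 0.14, 0.28, 0.56)        # ultrashort echoes, ms
CONVENTIONAL_ECHOES_MS = (7.16, 11.64, 16.12, 20.60)  # regular gradient echoes, ms
MT_TR_S = 0.015                                  # MT GRE repetition time, s
MT_FLIPS_DEG = (4.0, 24.0)                       # variable flip angles, degrees
ULTRASHORT_THRESHOLD_MS = 1.0                    # echoes below this are "ultrashort"

#: parameters whose ground-truth/fitted maps the pipeline carries
MAP_NAMES = (
    "S0", "f", "D", "Dstar", "ADC", "fDstar",
    "T2s_short", "T2s_long", "S0s", "S0l", "ratio",
    "T1", "T1s", "MTR", "ka", "delta",
)


@dataclass(frozen=True)
class AcquisitionSpec:
    """Per-modality acquisition parameters.

    Only the fields relevant to a given modality are populated; the JSON
    sidecar written next to each NIfTI round-trips this object losslessly.
    """

    modality: str                       # "dwi" | "ute" | "mt"
    bvalues: tuple[float, ...] | None = None
    te_ms: tuple[float, ...] | None = None
    tr_s: float | None = None
    flip_deg: tuple[float, ...] | None = None
    mt_pulse: tuple[bool, ...] | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        for k in ("bvalues", "te_ms", "flip_deg", "mt_pulse"):
            if k in d:
                d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSpec":
        kw = dict(d)
        for k in ("bvalues", "te_ms", "flip_deg"):
            if kw.get(k) is not None:
                kw[k] = tuple(float(x) for x in kw[k])
        if kw.get("mt_pulse") is not None:
            kw["mt_pulse"] = tuple(bool(x) for x in kw["mt_pulse"])
        return cls(**kw)


@dataclass
class SignalStack:
    """A 4D magnitude image series (x, y, z, volume) plus its acquisition."""

    data: np.ndarray
    acq: AcquisitionSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"signal stack must be 4D, got shape {self.data.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


class ParameterMaps(dict):
    """Named voxel-wise parameter maps sharing one spatial grid.

    A thin dict of name -> 3D array; NaN is the out-of-mask / flagged-voxel
    sentinel throughout the pipeline.
    """

    def __init__(self, maps: dict[str, np.ndarray] | None = None):
        super().__init__()
        if maps:
            for k, v in maps.items():
                self[k] = np.asarray(v, dtype=float)
        shapes = {v.shape for v in self.values()}
        if len(shapes) > 1:
            raise ValueError(f"maps have inconsistent shapes: {shapes}")

    @property
    def spatial_shape(self):
        return next(iter(self.values())).shape if self else None


# ---------------------------------------------------------------------------
# NIfTI + JSON sidecar I/O


def save_stack(stack: SignalStack, path: str | Path) -> None:
    """Write a stack as NIfTI with a JSON sidecar of acquisition parameters."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(stack.data, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz or .nii
    sidecar = Path(str(sidecar) + ".json")
    sidecar.write_text(json.dumps(stack.acq.to_dict(), indent=2, sort_keys=True))


def load_stack(path: str | Path) -> SignalStack:
    path = Path(path)
    img = nib.load(str(path))
    sidecar = path.with_suffix("").with_suffix("")
    sidecar = Path(str(sidecar) + ".json")
    acq = AcquisitionSpec.from_dict(json.loads(sidecar.read_text()))
    return SignalStack(np.asarray(img.get_fdata()), acq)


def save_maps(maps: ParameterMaps, outdir: str | Path, prefix: str = "") -> list[Path]:
    """One NIfTI per parameter map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in sorted(maps.items()):
        p = outdir / f"{prefix}{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), str(p))
        written.append(p)
    return written


def load_maps(outdir: str | Path, prefix: str = "") -> ParameterMaps:
    outdir = Path(outdir)
    maps = {}
    for p in sorted(outdir.glob(f"{prefix}*.nii.gz")):
        name = p.name[len(prefix):].removesuffix(".nii.gz")
        maps[name] = np.asarray(nib.load(str(p)).get_fdata())
    return ParameterMaps(maps)
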