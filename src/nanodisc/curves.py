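"""Scattering-curve container and 3-column text I/O.

Files are whitespace-separated ``q  I  sigma`` tables (q in 1/A, intensities
on absolute scale in 1/cm) with optional ``#`` header lines carrying
``key=value`` metadata (label, concentration, temperature, contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CurveParseError(ValueError):
    pass


class CurveValidationError(ValueError):
    pass


@dataclass
class ScatteringCurve:
    q: np.ndarray  # 1/A, strictly increasing
    intensity: np.ndarray  # 1/cm
    sigma: np.ndarray  # 1/cm, > 0
    contrast: str = "xray"  # "xray" | "neutron"
    concentration: float | None = None  # particles per cm^3, None = unknown
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (len(self.q) == len(self.intensity) == len(self.sigma)):
            raise CurveValidationError("q, I and sigma must have equal length")
        if len(self.q) == 0:
            raise CurveValidationError("curve is empty")
        if np.any(np.diff(self.q) <= 0):
            raise CurveValidationError("q must be strictly increasing")
        bad = np.flatnonzero(self.sigma <= 0)
        if bad.size:
            raise CurveValidationError(f"sigma must be positive (row {bad[0] + 1})")
        if self.contrast not in ("xray", "neutron"):
            raise CurveValidationError(f"unknown contrast {self.contrast!r}")

    def __len__(self) -> int:
        return len(self.q)


def read_scattering(path, contrast: str = "xray") -> ScatteringCurve:
    """Read a 3-column curve file; ``#`` header lines may carry key=value pairs."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            if text.startswith("#"):
                body = text.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            parts = text.split()
            if len(parts) < 3:
                raise CurveParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError as exc:
                raise CurveParseError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise CurveParseError(f"{path}: no data rows")
    arr = np.array(rows)
    conc = None
    if "concentration" in meta and meta["concentration"] != "unknown":
        conc = float(meta["concentration"])
    contrast = meta.get("contrast", contrast)
    try:
        return ScatteringCurve(
            q=arr[:, 0],
            intensity=arr[:, 1],
            sigma=arr[:, 2],
            contrast=contrast,
            concentration=conc,
            label=meta.get("label", ""),
            metadata=meta,
        )
    except CurveValidationError as exc:
        raise CurveValidationError(f"{path}: {exc}") from None


def write_scattering(curve: ScatteringCurve, path) -> None:
    with open(path, "w") as fh:
        if curve.label:
            fh.write(f"# label = {curve.label}\n")
        fh.write(f"# contrast = {curve.contrast}\n")
        if curve.concentration is not None:
            fh.write(f"# concentration = {curve.concentration!r}\n")
        fh.write("# columns = q[1/A] I[1/cm] sigma[1/cm]\n")
        for q, i, s in zip(curve.q, curve.intensity, curve.sigma):
            fh.write(f"{q:.8e} {i:.8e} {s:.8e}\n")
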