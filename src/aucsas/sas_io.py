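"""I/O and validated containers for scattering profiles and AUC species tables.

File dialects
-------------
* Scattering profile: plain 3-column ASCII ``.dat`` (q, I, sigma), the de
  facto small-angle-scattering exchange format.  Whitespace or comma
  delimited; ``#`` and ``;`` start comments.  q in 1/Angstrom, I in 1/cm
  (absolute) or cm^2/mg (concentration normalized).
* Species table: CSV with columns ``s20w`` and ``weight_fraction`` plus a
  pragma comment line ``# friction_ratio = <value>``.
* Reconstruction report: JSON with a fixed schema (see
  :func:`write_report`).
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringProfile",
    "Species",
    "SpeciesDistribution",
    "read_profile",
    "write_profile",
    "read_species_table",
    "write_species_table",
    "write_report",
    "read_report",
]


@dataclass
class ScatteringProfile:
    """A one-dimensional scattering profile I(q) with standard errors.

    Attributes
    ----------
    q : ndarray
        Scattering-vector magnitudes, 1/Angstrom, strictly increasing, > 0.
    intensity : ndarray
        I(q) in 1/cm (absolute) or cm^2/mg if ``normalized``.
    sigma : ndarray
        Standard error of the intensity, same units.
    concentration : float or None
        Total mass concentration, mg/ml.
    normalized : bool
        True when intensity is per unit concentration, i(q) = I(q)/c.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or len(self.q) == 0:
            raise ValueError("q must be a non-empty 1-D array")
        if self.intensity.shape != self.q.shape or self.sigma.shape != self.q.shape:
            raise ValueError("q, intensity and sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")
        if self.normalized:
            if self.concentration is None or self.concentration <= 0:
                raise ValueError(
                    "a normalized profile requires a positive concentration"
                )

    def __len__(self) -> int:
        return len(self.q)

    def scaled(self, factor: float) -> "ScatteringProfile":
        """Profile with intensity and sigma multiplied by ``factor``."""
        return replace(
            self,
            q=self.q.copy(),
            intensity=self.intensity * factor,
            sigma=self.sigma * factor,
        )

    def to_normalized(self) -> "ScatteringProfile":
        """Concentration-normalized copy, i(q) = I(q)/c."""
        if self.normalized:
            return self
        if self.concentration is None or self.concentration <= 0:
            raise ValueError("cannot normalize without a positive concentration")
        out = self.scaled(1.0 / self.concentration)
        out.normalized = True
        return out


@dataclass(frozen=True)
class Species:
    """One sedimenting species from a c(s) analysis."""

    s20w: float
    weight_fraction: float
    molar_mass: float | None = None
    association_number: int | None = None

    def __post_init__(self) -> None:
        if self.s20w <= 0:
            raise ValueError("s20w must be positive")
        if not 0 < self.weight_fraction <= 1:
            raise ValueError("weight_fraction must be in (0, 1]")
        if self.association_number is not None and self.association_number < 1:
            raise ValueError("association_number must be >= 1")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError("molar_mass must be positive")


@dataclass
class SpeciesDistribution:
    """AUC species distribution: monomer-first list plus the shared f/f0."""

    species: list[Species]
    friction_ratio: float

    def __post_init__(self) -> None:
        if len(self.species) < 1:
            raise ValueError("need at least one species")
        if self.friction_ratio < 1.0:
            raise ValueError("friction_ratio must be >= 1")
        # monomer first: the species with the smallest s20w
        self.species = sorted(self.species, key=lambda sp: sp.s20w)
        total = sum(sp.weight_fraction for sp in self.species)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"weight fractions sum to {total:.4f}, too far from 1"
            )
        if abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"weight fractions sum to {total:.6f}; renormalizing",
                stacklevel=2,
            )
            self.species = [
                replace(sp, weight_fraction=sp.weight_fraction / total)
                for sp in self.species
            ]

    @property
    def monomer(self) -> Species:
        return self.species[0]

    @property
    def aggregate_fraction(self) -> float:
        """r_a = 1 - r_1, total weight fraction of aggregates."""
        return 1.0 - self.monomer.weight_fraction

    @property
    def has_masses(self) -> bool:
        return all(sp.molar_mass is not None for sp in self.species)

    @property
    def has_association_numbers(self) -> bool:
        return all(sp.association_number is not None for sp in self.species)


_COMMENT_CHARS = ("#", ";")


def _read_numeric_table(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Parse a whitespace- or comma-delimited numeric text file.

    Returns the numeric block (ragged rows dropped) and the comment lines.
    """
    comments: list[str] = []
    rows: list[list[float]] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(_COMMENT_CHARS):
            comments.append(stripped.lstrip("#; ").rstrip())
            continue
        for delim in (None, ","):
            parts = stripped.split(delim)
            try:
                rows.append([float(p) for p in parts if p != ""])
                break
            except ValueError:
                continue
        else:
            # non-numeric line (e.g. column headers) — treat as comment
            comments.append(stripped)
    if not rows:
        return np.empty((0, 0)), comments
    ncol = max(len(r) for r in rows)
    block = np.full((len(rows), ncol), np.nan)
    for i, r in enumerate(rows):
        block[i, : len(r)] = r
    return block, comments


def read_profile(
    path: str | Path,
    concentration: float | None = None,
    q_unit: str = "1/A",
) -> ScatteringProfile:
    """Read a 2- or 3-column scattering profile from a text file.

    Rows with non-finite or non-positive q are dropped (count logged);
    duplicate q values are merged by error-weighted averaging.  When the
    sigma column is missing it is synthesized as
    ``max(0.01*I(q), 1e-3 * min positive I)`` so downstream weighted fits
    stay defined.

    Parameters
    ----------
    q_unit : {"1/A", "1/nm"}
        Declared unit of the q column; "1/nm" values are multiplied by 0.1
        on load.  No other conversion is ever attempted.
    """
    block, _ = _read_numeric_table(path)
    if block.size == 0 or block.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 numeric columns (q, I)")
    q = block[:, 0]
    intensity = block[:, 1]
    if q_unit == "1/nm":
        q = q * 0.1
    elif q_unit != "1/A":
        raise ValueError(f"unknown q unit {q_unit!r}")
    if block.shape[1] >= 3 and np.isfinite(block[:, 2]).all():
        sigma = block[:, 2]
    else:
        floor = np.nanmin(np.where(intensity > 0, intensity, np.nan)) * 1e-3
        sigma = np.maximum(0.01 * np.abs(intensity), floor)
        logger.info("%s: no sigma column; synthesized fallback errors", path)
    keep = np.isfinite(q) & np.isfinite(intensity) & (q > 0)
    dropped = len(q) - int(keep.sum())
    if dropped:
        logger.warning("%s: dropped %d rows with non-finite or q<=0", path, dropped)
    q, intensity, sigma = q[keep], intensity[keep], sigma[keep]
    order = np.argsort(q, kind="stable")
    q, intensity, sigma = q[order], intensity[order], sigma[order]
    # merge duplicate q by inverse-variance weighting
    uq, inverse, counts = np.unique(q, return_inverse=True, return_counts=True)
    if len(uq) < len(q):
        logger.warning("%s: averaged %d duplicate q values", path, len(q) - len(uq))
        w = 1.0 / np.maximum(sigma, 1e-300) ** 2
        wsum = np.bincount(inverse, weights=w)
        intensity = np.bincount(inverse, weights=w * intensity) / wsum
        sigma = 1.0 / np.sqrt(wsum)
        q = uq
    if len(q) < 10:
        raise ValueError(f"{path}: fewer than 10 usable rows")
    return ScatteringProfile(
        q=q, intensity=intensity, sigma=sigma, concentration=concentration
    )


def write_profile(profile: ScatteringProfile, path: str | Path) -> None:
    """Write a profile as 3-column text with a unit/normalization header."""
    unit = "cm^2/mg" if profile.normalized else "1/cm"
    lines = [
        f"# q(1/A) I({unit}) sigma({unit})",
        f"# normalized = {profile.normalized}",
    ]
    if profile.concentration is not None:
        lines.append(f"# concentration_mg_ml = {profile.concentration:.6g}")
    buf = io.StringIO()
    np.savetxt(
        buf,
        np.column_stack([profile.q, profile.intensity, profile.sigma]),
        fmt="%.8e",
    )
    Path(path).write_text("\n".join(lines) + "\n" + buf.getvalue())


def read_species_table(path: str | Path) -> SpeciesDistribution:
    """Read an AUC species table (CSV + ``# friction_ratio = x`` pragma)."""
    text = Path(path).read_text()
    friction_ratio = None
    for line in text.splitlines():
        stripped = line.strip()
        if stripped.startswith(_COMMENT_CHARS) and "friction_ratio" in stripped:
            friction_ratio = float(stripped.split("=")[1])
    if friction_ratio is None:
        raise ValueError(f"{path}: missing '# friction_ratio = <value>' pragma")
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    df.columns = [c.strip().lower() for c in df.columns]
    if "s20w" not in df.columns or "weight_fraction" not in df.columns:
        raise ValueError(f"{path}: need columns 's20w' and 'weight_fraction'")
    species = []
    for _, row in df.iterrows():
        mass = row.get("molar_mass")
        mass = None if mass is None or pd.isna(mass) else float(mass)
        species.append(
            Species(
                s20w=float(row["s20w"]),
                weight_fraction=float(row["weight_fraction"]),
                molar_mass=mass,
            )
        )
    return SpeciesDistribution(species=species, friction_ratio=friction_ratio)


def write_species_table(dist: SpeciesDistribution, path: str | Path) -> None:
    lines = [f"# friction_ratio = {dist.friction_ratio:.6g}"]
    cols = "s20w,weight_fraction"
    with_mass = dist.has_masses
    if with_mass:
        cols += ",molar_mass"
    lines.append(cols)
    for sp in dist.species:
        row = f"{sp.s20w:.9g},{sp.weight_fraction:.9g}"
        if with_mass:
            row += f",{sp.molar_mass:.9g}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(result, path: str | Path, seed: int | None = None) -> None:
    """Write a JSON reconstruction report.

    Schema (keys always present unless noted): ``method``, ``rg1_A``,
    ``rg1_sd_A``, ``I1_zero``, ``I1_zero_sd``, ``i1_zero``, ``i1_zero_sd``,
    ``q_connect``, ``qc_rg1``, ``iterations``, ``warnings``, ``species``
    (echo of the table), ``software``; optional: ``dmax_A``, ``pr_file``,
    ``seed``.
    """
    from . import __version__

    doc = {
        "method": result.method,
        "rg1_A": result.rg1,
        "rg1_sd_A": result.rg1_sd,
        "I1_zero": result.I1_zero,
        "I1_zero_sd": result.I1_zero_sd,
        "i1_zero": result.i1_zero,
        "i1_zero_sd": result.i1_zero_sd,
        "q_connect": result.q_connect,
        "qc_rg1": result.q_connect * result.rg1,
        "iterations": result.iterations,
        "warnings": list(result.warnings),
        "species": [
            {
                "s20w": sp.s20w,
                "weight_fraction": sp.weight_fraction,
                "molar_mass": sp.molar_mass,
                "association_number": sp.association_number,
            }
            for sp in result.distribution.species
        ]
        if result.distribution is not None
        else [],
        "software": f"aucsas {__version__}",
    }
    if getattr(result, "dmax", None) is not None:
        doc["dmax_A"] = result.dmax
    if seed is not None:
        doc["seed"] = seed
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
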