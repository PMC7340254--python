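"""One-dimensional SAXS profiles, titration series and experiment sets.

All momentum-transfer values are stored in nm^-1 internally.  Files written
in the Angstrom convention are converted on read via the ``unit`` argument,
so a profile object never carries an ambiguous q scale.
"""

from __future__ import annotations

import csv
import io
import pathlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml


class ProfileParseError(ValueError):
    """Raised when a profile file cannot be interpreted as (q, I[, sigma])."""


class ProfileRangeError(ValueError):
    """Raised when a requested q-grid or q-window leaves the measured range."""


class DegenerateSetError(ValueError):
    """Raised when an averaging step is left with no usable profiles."""


@dataclass
class ScatteringProfile:
    """A buffer-subtracted 1D scattering curve I(q) with optional errors.

    Parameters
    ----------
    q : array
        Momentum transfer in nm^-1, strictly increasing and nonnegative.
    I : array
        Excess scattered intensity, arbitrary units.
    sigma : array or None
        Per-point 1-sigma intensity uncertainty, same units as ``I``.
    label : str
        Free-text identifier (file stem, ligand/ratio tag, ...).
    receptor_concentration : float or None
        Molar receptor concentration of the sample, if known.
    exposure_metadata : dict
        Free-form acquisition metadata (dose, frames, beamline).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    receptor_concentration: float | None = None
    exposure_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        self._validate()

    def _validate(self) -> None:
        if self.q.ndim != 1 or self.I.shape != self.q.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match q in length")
        if len(self.q) and np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if len(self.q) and self.q[0] < 0:
            raise ValueError("q must be nonnegative")
        if self.sigma is not None and np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")

    def __len__(self) -> int:
        return len(self.q)

    def copy(self) -> "ScatteringProfile":
        return replace(
            self,
            q=self.q.copy(),
            I=self.I.copy(),
            sigma=None if self.sigma is None else self.sigma.copy(),
            exposure_metadata=dict(self.exposure_metadata),
        )


@dataclass
class TitrationPoint:
    ratio: float
    profile: ScatteringProfile
    excluded: bool = False
    reason: str | None = None


@dataclass
class TitrationSeries:
    """Ordered titration points of one ligand at fixed receptor concentration."""

    ligand_id: str
    receptor_concentration: float
    points: list[TitrationPoint]

    def __post_init__(self) -> None:
        ratios = [p.ratio for p in self.points]
        if any(r < 0 for r in ratios):
            raise ValueError("ligand:receptor ratios must be nonnegative")
        if ratios != sorted(ratios):
            raise ValueError("titration points must be in nondecreasing ratio order")

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    def active_points(self) -> list[TitrationPoint]:
        return [p for p in self.points if not p.excluded]


@dataclass
class ExperimentSet:
    """All titrations of one session at one receptor concentration."""

    series: list[TitrationSeries]
    apo_profiles: list[ScatteringProfile]
    q_window: tuple[float, float]
    d_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        qmin, qmax = self.q_window
        if qmin >= qmax:
            raise ValueError("q_window must be (q_min, q_max) with q_min < q_max")

    @property
    def receptor_concentration(self) -> float:
        return self.series[0].receptor_concentration


# ---------------------------------------------------------------------------
# File I/O


def read_profile(
    path: str | pathlib.Path,
    unit: str = "nm^-1",
    label: str | None = None,
) -> ScatteringProfile:
    """Read a 3-column ``.dat`` text profile (q, I [, sigma]).

    Header and comment lines are tolerated: any line whose fields do not all
    parse as numbers is skipped, except inside the numeric body, where it is
    an error.  ``unit`` may be ``"nm^-1"`` (native) or ``"A^-1"``; Angstrom
    grids are multiplied by 10 so internal q is always nm^-1.
    """
    path = pathlib.Path(path)
    rows: list[tuple[float, ...]] = []
    in_body = False
    ncols = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", ";")):
            continue
        fields = stripped.split()
        try:
            values = tuple(float(x) for x in fields)
        except ValueError:
            if in_body:
                # footer sections (ATSAS files append fit metadata) end the body
                break
            continue
        if len(values) < 2:
            raise ProfileParseError(f"{path}:{lineno}: fewer than 2 numeric columns")
        if ncols is None:
            ncols = len(values)
        in_body = True
        rows.append(values[: min(ncols, 3)])
    if not rows:
        raise ProfileParseError(f"{path}: no numeric data rows found")

    arr = np.array([r + (np.nan,) * (3 - len(r)) for r in rows])
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # drop exact duplicate q values, then demand monotonicity
    keep = np.concatenate([[True], np.diff(arr[:, 0]) > 0])
    arr = arr[keep]
    if len(arr) > 1 and np.any(np.diff(arr[:, 0]) <= 0):
        raise ProfileParseError(f"{path}: q not strictly increasing after sorting")

    q = arr[:, 0]
    if unit in ("A^-1", "angstrom", "Å^-1"):
        q = q * 10.0
    elif unit not in ("nm^-1", "nm"):
        raise ValueError(f"unknown q unit {unit!r}")
    sigma = arr[:, 2]
    has_sigma = not np.all(np.isnan(sigma))
    return ScatteringProfile(
        q=q,
        I=arr[:, 1],
        sigma=np.nan_to_num(sigma) if has_sigma else None,
        label=label if label is not None else path.stem,
    )


def write_profile(profile: ScatteringProfile, path: str | pathlib.Path) -> None:
    """Write a profile as 3-column (or 2-column) whitespace text, q in nm^-1."""
    path = pathlib.Path(path)
    with path.open("w") as fh:
        fh.write(f"# {profile.label}\n# q(nm^-1)  I(q)  sigma\n")
        for i in range(len(profile)):
            if profile.sigma is not None:
                fh.write(
                    f"{profile.q[i]:.8e} {profile.I[i]:.8e} {profile.sigma[i]:.8e}\n"
                )
            else:
                fh.write(f"{profile.q[i]:.8e} {profile.I[i]:.8e}\n")


# ---------------------------------------------------------------------------
# Grid handling


def resample_to_grid(
    profile: ScatteringProfile, grid: Sequence[float]
) -> ScatteringProfile:
    """Linearly interpolate I (and sigma) onto ``grid``; never extrapolates."""
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ProfileRangeError("empty target grid")
    if grid.min() < profile.q[0] or grid.max() > profile.q[-1]:
        raise ProfileRangeError(
            f"grid [{grid.min():g}, {grid.max():g}] outside measured "
            f"range [{profile.q[0]:g}, {profile.q[-1]:g}]"
        )
    I = np.interp(grid, profile.q, profile.I)
    sigma = (
        None if profile.sigma is None else np.interp(grid, profile.q, profile.sigma)
    )
    return replace(profile, q=grid, I=I, sigma=sigma)


def truncate_profile(
    profile: ScatteringProfile, window: tuple[float, float]
) -> ScatteringProfile:
    qmin, qmax = window
    mask = (profile.q >= qmin) & (profile.q <= qmax)
    if not np.any(mask):
        raise ProfileRangeError(
            f"window ({qmin:g}, {qmax:g}) leaves no points of {profile.label!r}"
        )
    return replace(
        profile,
        q=profile.q[mask],
        I=profile.I[mask],
        sigma=None if profile.sigma is None else profile.sigma[mask],
    )


def apply_q_window(
    series: TitrationSeries, window: tuple[float, float]
) -> TitrationSeries:
    """Truncate every profile of a series to [q_min, q_max], inclusive."""
    points = [
        TitrationPoint(
            ratio=p.ratio,
            profile=truncate_profile(p.profile, window),
            excluded=p.excluded,
            reason=p.reason,
        )
        for p in series.points
    ]
    return TitrationSeries(series.ligand_id, series.receptor_concentration, points)


# ---------------------------------------------------------------------------
# Apo reference


def build_apo_reference(
    apo_profiles: Sequence[ScatteringProfile],
    outlier_threshold: float = 0.1,
    d_max: float = 7.2,
) -> tuple[ScatteringProfile, list[str]]:
    """Average apo replicates into the reference curve J(q).

    Replicates whose volatility ratio against the pointwise *median* profile
    exceeds ``outlier_threshold`` are discarded before the pointwise mean is
    taken; the default threshold 0.1 is the practical detectability floor of
    the metric.  Returns (reference, labels of discarded replicates).
    """
    from .metrics import shannon_binning, volatility_ratio  # cycle-free at runtime

    if not apo_profiles:
        raise DegenerateSetError("no apo profiles given")
    q0 = apo_profiles[0].q
    for p in apo_profiles[1:]:
        if len(p.q) != len(q0) or not np.allclose(p.q, q0):
            raise ValueError("apo profiles must share a common q-grid")

    if len(apo_profiles) == 1:
        return apo_profiles[0].copy(), []

    stack = np.vstack([p.I for p in apo_profiles])
    median = ScatteringProfile(q=q0, I=np.median(stack, axis=0), label="median")
    binning = shannon_binning((q0[0], q0[-1]), q0, d_max)
    kept, discarded = [], []
    for p in apo_profiles:
        vr, _ = volatility_ratio(p, median, binning, fit_c=False)
        if vr > outlier_threshold:
            discarded.append(p.label)
        else:
            kept.append(p)
    if not kept:
        raise DegenerateSetError("all apo replicates discarded as outliers")

    mean_I = np.mean(np.vstack([p.I for p in kept]), axis=0)
    sigmas = [p.sigma for p in kept if p.sigma is not None]
    if len(sigmas) == len(kept):
        # uncertainty of the mean of independent replicates
        mean_sigma = np.sqrt(np.sum(np.vstack(sigmas) ** 2, axis=0)) / len(kept)
    else:
        mean_sigma = None
    ref = ScatteringProfile(
        q=q0.copy(),
        I=mean_I,
        sigma=mean_sigma,
        label=f"apo_reference(n={len(kept)})",
        receptor_concentration=apo_profiles[0].receptor_concentration,
    )
    return ref, discarded


# ---------------------------------------------------------------------------
# Manifests


def load_manifest(path: str | pathlib.Path, base_dir=None) -> ExperimentSet:
    """Load an experiment set from a YAML or CSV manifest.

    YAML schema::

        label: desy-80uM          # optional
        receptor_concentration: 8.0e-5   # molar
        d_max: 7.2                # nm
        q_window: [0.3, 3.0]      # nm^-1
        q_unit: nm^-1             # or A^-1, applied to all files
        series:
          - ligand: His
            points:
              - {file: his_00.dat, ratio: 0.0}
              - {file: his_10.dat, ratio: 1.0, excluded: true, reason: bubble}

    CSV manifests carry columns ``ligand,ratio,file[,excluded,reason]`` and
    take the set-level fields from same-named ``#key: value`` header comments.
    Every ratio-0 profile across all series doubles as an apo replicate; an
    optional top-level ``apo_files:`` list adds further apo-only wells to
    the reference pool.
    """
    path = pathlib.Path(path)
    base = pathlib.Path(base_dir) if base_dir is not None else path.parent
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text())
    else:
        doc = _csv_manifest_to_doc(path)

    unit = doc.get("q_unit", "nm^-1")
    conc = float(doc["receptor_concentration"])
    series_list = []
    apo: list[ScatteringProfile] = []
    for s in doc["series"]:
        points = []
        for entry in s["points"]:
            prof = read_profile(base / entry["file"], unit=unit)
            prof.receptor_concentration = conc
            prof.label = f"{s['ligand']}@{float(entry['ratio']):g}:{prof.label}"
            pt = TitrationPoint(
                ratio=float(entry["ratio"]),
                profile=prof,
                excluded=bool(entry.get("excluded", False)),
                reason=entry.get("reason"),
            )
            points.append(pt)
            if pt.ratio == 0 and not pt.excluded:
                apo.append(prof)
        points.sort(key=lambda p: p.ratio)
        series_list.append(TitrationSeries(s["ligand"], conc, points))
    for fname in doc.get("apo_files", []) or []:
        prof = read_profile(base / fname, unit=unit)
        prof.receptor_concentration = conc
        apo.append(prof)
    if not apo:
        raise ValueError(f"{path}: manifest contains no usable apo (ratio 0) point")
    return ExperimentSet(
        series=series_list,
        apo_profiles=apo,
        q_window=tuple(float(x) for x in doc["q_window"]),
        d_max=float(doc["d_max"]),
        label=str(doc.get("label", path.stem)),
    )


def _csv_manifest_to_doc(path: pathlib.Path) -> dict:
    meta: dict = {}
    body = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = yaml.safe_load(val.strip())
            continue
        body.append(line)
    reader = csv.DictReader(io.StringIO("\n".join(body)))
    per_ligand: dict[str, list] = {}
    for row in reader:
        per_ligand.setdefault(row["ligand"], []).append(
            {
                "file": row["file"],
                "ratio": float(row["ratio"]),
                "excluded": str(row.get("excluded", "")).lower() in ("1", "true", "yes"),
                "reason": row.get("reason") or None,
            }
        )
    meta["series"] = [
        {"ligand": lig, "points": pts} for lig, pts in per_ligand.items()
    ]
    return meta


def common_grid(profiles: Iterable[ScatteringProfile]) -> np.ndarray:
    """The q-grid of the coarsest profile, clipped to the shared range."""
    profiles = list(profiles)
    lo = max(p.q[0] for p in profiles)
    hi = min(p.q[-1] for p in profiles)
    if lo >= hi:
        raise ProfileRangeError("profiles share no overlapping q-range")
    coarsest = min(profiles, key=lambda p: len(p.q))
    mask = (coarsest.q >= lo) & (coarsest.q <= hi)
    return coarsest.q[mask]


def prepare_experiment(expt: ExperimentSet) -> ExperimentSet:
    """Put every profile of the set onto one grid inside the q-window."""
    all_profiles = [p.profile for s in expt.series for p in s.points]
    all_profiles += expt.apo_profiles
    grid = common_grid(all_profiles)
    qmin, qmax = expt.q_window
    grid = grid[(grid >= qmin) & (grid <= qmax)]
    if len(grid) < 2:
        raise ProfileRangeError("q_window leaves fewer than 2 shared grid points")
    series = []
    for s in expt.series:
        pts = [
            TitrationPoint(
                p.ratio, resample_to_grid(p.profile, grid), p.excluded, p.reason
            )
            for p in s.points
        ]
        series.append(TitrationSeries(s.ligand_id, s.receptor_concentration, pts))
    apo = [resample_to_grid(p, grid) for p in expt.apo_profiles]
    return ExperimentSet(series, apo, (grid[0], grid[-1]), expt.d_max, expt.label)
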