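"""Two-state mixture theory: Debye profiles and metric-vs-population sweeps.

Because dilute particles scatter independently, a mixture of two conformers
contributes intensities linearly: I_mix(q) = (1-f) I_A(q) + f I_B(q).  The
modules's sweep machinery quantifies how *metrics* computed from the mixed
curve respond to the population fraction f — exactly linear for metrics
that are linear functionals of I (such as I(0)), and quasi-linear for V_R
and V_c when the endpoints are similar-sized globular particles.

Profiles from atomic coordinates use the Debye sum with constant
per-element electron-count weights (a vacuum engine: no hydration layer or
excluded-volume term, which do not affect mixing linearity):

    I(q) = sum_ij f_i f_j sinc(q r_ij),   I(0) = (sum_i f_i)^2,

accelerated by a pair-distance histogram with bin width <= 0.01 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import (
    guinier_rg,
    invariants_vc_vp,
    shannon_binning,
    volatility_ratio,
    chi_lin,
)
from .profiles import ScatteringProfile

__all__ = [
    "ConformerPair",
    "MixtureSweep",
    "ELECTRON_COUNTS",
    "debye_profile",
    "mix_profiles",
    "metric_vs_population",
]

# electron counts used as q-independent form-factor weights
ELECTRON_COUNTS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "NA": 11, "MG": 12, "P": 15, "S": 16,
    "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26, "CO": 27, "NI": 28,
    "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}


@dataclass
class ConformerPair:
    profile_A: ScatteringProfile
    profile_B: ScatteringProfile
    label_A: str = "A"
    label_B: str = "B"

    def __post_init__(self) -> None:
        if len(self.profile_A.q) != len(self.profile_B.q) or not np.allclose(
            self.profile_A.q, self.profile_B.q
        ):
            raise ValueError("conformer profiles must share a q-grid")


def debye_profile(
    coordinates,
    q_grid,
    histogram_bin_nm: float = 0.01,
    label: str = "debye",
) -> ScatteringProfile:
    """Orientationally averaged intensity of one rigid structure.

    ``coordinates`` is either a path to a PDB/mmCIF file (read with gemmi)
    or a tuple ``(positions_nm, elements)`` with positions in nm.  Unknown
    elements raise with the offending symbols listed.
    """
    q = np.asarray(q_grid, dtype=float)
    if np.any(q < 0):
        raise ValueError("q_grid must be nonnegative")
    pos, elements = _load_coordinates(coordinates)
    unknown = sorted({e for e in elements if e.upper() not in ELECTRON_COUNTS})
    if unknown:
        raise ValueError(f"unknown element(s) in model: {', '.join(unknown)}")
    f = np.array([ELECTRON_COUNTS[e.upper()] for e in elements], dtype=float)

    centers, hist = _pair_histogram(pos, f, histogram_bin_nm)
    # I(q) = sum_i f_i^2 + 2 * sum_{i<j} f_i f_j sinc(q r_ij)
    self_term = float(np.sum(f**2))
    qr = np.outer(q, centers)
    I = self_term + 2.0 * (np.sinc(qr / np.pi) @ hist)
    return ScatteringProfile(q=q, I=I, label=label)


def _load_coordinates(coordinates):
    if isinstance(coordinates, tuple):
        pos, elements = coordinates
        return np.asarray(pos, dtype=float), list(elements)
    import gemmi

    st = gemmi.read_structure(str(coordinates))
    st.setup_entities()
    pos, elements = [], []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                pos.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
    return np.asarray(pos) / 10.0, elements  # Angstrom -> nm


def _pair_histogram(pos: np.ndarray, f: np.ndarray, bin_nm: float):
    """f_i f_j-weighted histogram of distinct pair distances, chunked."""
    n = len(pos)
    if n < 2:
        return np.array([]), np.array([])
    # conservative upper bound on the diameter from the bounding box
    span = np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)) + bin_nm
    nbins = max(int(np.ceil(span / bin_nm)), 1)
    edges = np.linspace(0.0, nbins * bin_nm, nbins + 1)
    hist = np.zeros(nbins)
    chunk = max(1, int(5e6) // max(n, 1))
    for start in range(0, n, chunk):
        block = pos[start : start + chunk]
        d = np.sqrt(
            np.maximum(
                ((block[:, None, :] - pos[None, :, :]) ** 2).sum(-1), 0.0
            )
        )
        w = np.outer(f[start : start + chunk], f)
        # mask to i<j pairs only
        rows = np.arange(start, start + len(block))[:, None]
        cols = np.arange(n)[None, :]
        m = cols > rows
        h, _ = np.histogram(d[m], bins=edges, weights=w[m])
        hist += h
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = hist != 0
    return centers[keep], hist[keep]


@dataclass
class MixtureSweep:
    fractions: np.ndarray
    metric_values: dict[str, np.ndarray]
    linear_fit: dict[str, tuple[float, float]]
    max_deviation_pct: dict[str, float]
    degenerate: bool = False
    notes: dict = field(default_factory=dict)


def mix_profiles(pair: ConformerPair, f: float, weighting: str = "number") -> ScatteringProfile:
    """Pointwise intensity mixture at bound fraction f in [0, 1].

    ``number`` weighting mixes per-particle intensities directly; ``mass``
    weighting re-scales the fractions by I(0) (proportional to particle
    mass squared per particle, i.e. equal-mass rather than equal-count
    mixing), which matters only for strongly unequal-size endpoints such as
    oligomerization transitions.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if weighting == "number":
        wa, wb = 1.0 - f, f
    elif weighting == "mass":
        ia0, ib0 = pair.profile_A.I[0], pair.profile_B.I[0]
        # equal total mass: number fraction inversely proportional to size
        na = (1.0 - f) / np.sqrt(ia0)
        nb = f / np.sqrt(ib0)
        wa, wb = na / (na + nb), nb / (na + nb)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    I = wa * pair.profile_A.I + wb * pair.profile_B.I
    return ScatteringProfile(
        q=pair.profile_A.q.copy(), I=I, label=f"mix(f={f:g})"
    )


def metric_vs_population(
    pair: ConformerPair,
    metrics: list[str] = ("V_R", "R_g", "V_c"),
    n_fractions: int = 101,
    vr_q_window: tuple[float, float] | None = None,
    d_max: float = 7.2,
    weighting: str = "number",
) -> MixtureSweep:
    """Sweep each metric along the population fraction and rate linearity.

    V_R and chi_lin are referenced to the f = 0 profile.  For every metric
    an ordinary least-squares line is fitted over f and the maximum
    |residual| reported as a percentage of the endpoint-to-endpoint metric
    change — the linearity figure of merit.  Identical endpoints make the
    change zero; the sweep is then flagged degenerate.
    """
    fractions = np.linspace(0.0, 1.0, n_fractions)
    q = pair.profile_A.q
    window = vr_q_window or (q[0], q[-1])
    degenerate = bool(np.allclose(pair.profile_A.I, pair.profile_B.I))

    binning = None
    if "V_R" in metrics and not degenerate:
        sel = (q >= window[0]) & (q <= window[1])
        binning = shannon_binning((q[sel][0], q[sel][-1]), q, d_max)
    reference = mix_profiles(pair, 0.0, weighting)

    values: dict[str, list[float]] = {m: [] for m in metrics}
    for f in fractions:
        mixed = mix_profiles(pair, f, weighting)
        for m in metrics:
            if degenerate:
                values[m].append(0.0 if m in ("V_R", "chi_lin") else np.nan)
                continue
            if m == "V_R":
                v, _ = volatility_ratio(mixed, reference, binning)
            elif m == "chi_lin":
                v, _ = chi_lin(mixed, reference)
            elif m == "R_g":
                v = guinier_rg(mixed)[0]
            elif m in ("V_c", "V_P"):
                g = guinier_rg(mixed)
                vc, vp = invariants_vc_vp(mixed, g)
                v = vc if m == "V_c" else vp
            else:
                raise ValueError(f"unknown metric {m!r}")
            values[m].append(v)

    metric_values = {m: np.array(v) for m, v in values.items()}
    linear_fit, deviation = {}, {}
    for m, v in metric_values.items():
        if degenerate or not np.all(np.isfinite(v)):
            linear_fit[m] = (0.0, float(np.nanmean(v)) if len(v) else 0.0)
            deviation[m] = float("nan")
            continue
        slope, intercept = np.polyfit(fractions, v, 1)
        resid = v - (slope * fractions + intercept)
        total_change = abs(v[-1] - v[0])
        linear_fit[m] = (float(slope), float(intercept))
        deviation[m] = (
            float(np.max(np.abs(resid)) / total_change * 100.0)
            if total_change > 0
            else float("nan")
        )
    return MixtureSweep(
        fractions=fractions,
        metric_values=metric_values,
        linear_fit=linear_fit,
        max_deviation_pct=deviation,
        degenerate=degenerate,
        notes={"weighting": weighting, "vr_q_window": window, "d_max": d_max},
    )
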