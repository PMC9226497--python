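"""Shrake-Rupley solvent-accessible surface area and uptake correlations.

SASA is computed by sphere-point sampling on a fixed Fibonacci lattice
(deterministic for a given point count): a point on atom i's solvent-
expanded sphere (r_i + probe) is accessible if it lies outside every
neighbor's expanded sphere, and the atom's SASA is the accessible fraction
of its sphere area.  Van der Waals radii are the Bondi set shipped as a
data file.

Per-peptide backbone SASA (sum over N, CA, C, O and the amide H when
present) is correlated against experimental maximum uptake by ordinary
least squares, with studentized-residual outlier candidates surfaced but
never auto-removed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .io import Peptide, _load_structure

PROBE_RADIUS_A = 1.4
N_POINTS = 960
BACKBONE_ATOMS = ("N", "CA", "C", "O", "H")


def _load_radii() -> dict[str, float]:
    table = {}
    ref = resources.files("hdxpipe.data") / "bondi_radii.csv"
    with ref.open() as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#") and r[0] != "element"]
    for elem, radius in rows:
        table[elem.upper()] = float(radius)
    return table


VDW_RADII = _load_radii()


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice of n points."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    atom_sasa: np.ndarray          # A^2 per atom
    structure: object              # biotite AtomArray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_sasa.sum())


def shrake_rupley(structure, probe_radius: float = PROBE_RADIUS_A,
                  n_points: int = N_POINTS) -> SasaResult:
    """Per-atom SASA of a structure (PDB path, text, or AtomArray)."""
    arr = _load_structure(structure)
    elements = [str(e).upper() for e in arr.element]
    unknown = sorted({e for e in elements if e not in VDW_RADII})
    if unknown:
        bad = next(i for i, e in enumerate(elements) if e in unknown)
        raise ValueError(
            f"no van der Waals radius for element(s) {unknown} "
            f"(first at atom {bad}: {arr.atom_name[bad]})")
    radii = np.array([VDW_RADII[e] for e in elements]) + probe_radius
    coords = np.asarray(arr.coord, dtype=float)
    n_atoms = len(coords)
    sphere = fibonacci_sphere(n_points)
    # deterministic per-atom lattice orientation (fixed internal seed, a
    # function of atom order only, hence invariant under rigid motions of
    # the structure): decorrelates discretization error between atoms so
    # totals converge much faster than with a single shared orientation
    orient_rng = np.random.default_rng(1905)
    tree = cKDTree(coords)
    max_r = radii.max()
    sasa = np.zeros(n_atoms)
    for i in range(n_atoms):
        rot, _ = np.linalg.qr(orient_rng.normal(size=(3, 3)))
        pts = coords[i] + radii[i] * (sphere @ rot.T)
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_r)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > radii[j] ** 2
        sasa[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(sasa, arr, probe_radius, n_points)


def backbone_peptide_sasa(sasa: SasaResult, peptide_map: list[Peptide],
                          atoms: tuple[str, ...] = BACKBONE_ATOMS,
                          ) -> pd.DataFrame:
    """Sum backbone-atom SASA over each peptide's residues.

    Peptides with any residue absent from the structure are flagged
    (``complete`` False); a peptide fully missing gets NaN.
    """
    arr = sasa.structure
    res_ids = np.asarray(arr.res_id)
    atom_names = np.asarray(arr.atom_name)
    present = set(res_ids.tolist())
    rows = []
    for pep in peptide_map:
        wanted = set(range(pep.start, pep.end + 1))
        missing = sorted(wanted - present)
        found = wanted & present
        if found:
            mask = np.isin(res_ids, list(found)) & np.isin(atom_names, atoms)
            value = float(sasa.atom_sasa[mask].sum())
        else:
            value = np.nan
        rows.append({
            "protein": pep.protein_id,
            "start": pep.start, "end": pep.end,
            "backbone_sasa_A2": value,
            "complete": not missing,
            "missing_residues": ";".join(map(str, missing)),
        })
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    n: int
    r: float
    r2: float
    slope: float
    intercept: float
    excluded: list = field(default_factory=list)


def correlate(x, y, ids=None, exclude: list | None = None,
              ) -> CorrelationResult:
    """Least-squares line and Pearson r^2 on the included points.

    ``ids`` names the points (defaults to 0..n-1); ``exclude`` lists ids to
    drop before fitting, echoed in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = list(ids) if ids is not None else list(range(len(x)))
    exclude = list(exclude or [])
    keep = np.array([i not in set(exclude) for i in ids])
    keep &= np.isfinite(x) & np.isfinite(y)
    xk, yk = x[keep], y[keep]
    if len(xk) < 3:
        raise ValueError(f"need >= 3 included points, got {len(xk)}")
    if np.ptp(xk) == 0 or np.ptp(yk) == 0:
        raise ValueError("zero variance in x or y")
    fit = linregress(xk, yk)
    return CorrelationResult(n=len(xk), r=float(fit.rvalue),
                             r2=float(fit.rvalue ** 2),
                             slope=float(fit.slope),
                             intercept=float(fit.intercept),
                             excluded=exclude)


def flag_outliers(x, y, ids=None, threshold: float = 2.5) -> list:
    """Candidate outliers by |internally studentized residual| > threshold.

    Candidates are sorted by magnitude and only surfaced: removal stays an
    explicit, caller-side decision.
    """
    import statsmodels.api as sm
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = list(ids) if ids is not None else list(range(len(x)))
    if len(x) < 5:
        raise ValueError("need >= 5 points for outlier screening")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid = model.get_influence().resid_studentized_internal
    order = np.argsort(-np.abs(resid))
    return [ids[i] for i in order if abs(resid[i]) > threshold]
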