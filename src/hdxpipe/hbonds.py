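"""Amide H-bond classification from MD and logistic protection factors.

Each backbone amide is classified per trajectory frame as hydrogen-bonded
to the protein and/or to water (geometric criterion: donor N to acceptor
heavy-atom distance <= 3.5 A and H-N...acceptor angle <= 30 deg).  The
fraction of frames in which the amide is "closed" (default observable:
protein-bonded and not water-bonded) maps to a protection factor through a
logistic growth curve in the closed fraction x,

    ln PF = L / (1 + exp(-s * (x - x0)))

whose parameters (ceiling L, midpoint x0, steepness s) can be calibrated
against experimental uptake.  Deuteration then follows EX2 kinetics,
D_i(t) = 1 - exp(-k_int,i * t / PF_i), aggregated to peptides for direct
comparison with measured tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Peptide, UptakeTable, CANONICAL_COLUMNS
from .rates import ResidueRates

logger = logging.getLogger(__name__)

D_CUT_A = 3.5
THETA_CUT_DEG = 30.0
WATER_RESNAMES = {"HOH", "WAT", "TIP3", "TIP", "SOL", "SPC", "H2O"}


@dataclass
class AmideHBondSeries:
    """Per-frame H-bond flags of one backbone amide."""

    residue: int
    bonded_to_protein: np.ndarray   # bool per frame
    bonded_to_water: np.ndarray

    def __post_init__(self):
        self.bonded_to_protein = np.asarray(self.bonded_to_protein, bool)
        self.bonded_to_water = np.asarray(self.bonded_to_water, bool)
        if self.bonded_to_protein.shape != self.bonded_to_water.shape:
            raise ValueError("flag arrays differ in length")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def n_frames(self) -> int:
        return len(self.bonded_to_protein)

    def closed_fraction(self, mode: str = "protein_not_water") -> float:
        if mode == "protein_not_water":
            closed = self.bonded_to_protein & ~self.bonded_to_water
        elif mode == "protein_only":
            closed = self.bonded_to_protein
        else:
            raise ValueError(f"unknown mode {mode!r}")
        return float(np.mean(closed))


@dataclass
class LogisticParams:
    """Logistic map from closed fraction to ln PF."""

    L: float      # ceiling of ln PF
    x0: float     # midpoint closed fraction
    s: float      # steepness

    def __post_init__(self):
        if self.L <= 0 or self.s <= 0 or not 0.0 <= self.x0 <= 1.0:
            raise ValueError(
                f"invalid logistic parameters L={self.L}, x0={self.x0}, "
                f"s={self.s}")

    def ln_pf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.L / (1.0 + np.exp(-self.s * (x - self.x0)))


@dataclass
class ProtectionProfile:
    """Per-residue closed fraction and protection factor."""

    closed_fraction: dict[int, float]
    pf: dict[int, float]
    params: LogisticParams
    n_frames: int
    mode: str = "protein_not_water"


def classify_hbonds(topology, trajectory=None, d_cut: float = D_CUT_A,
                    theta_cut_deg: float = THETA_CUT_DEG,
                    stride: int = 1) -> dict[int, AmideHBondSeries]:
    """Classify backbone-amide H bonds over an MD trajectory.

    ``topology`` is a PDB (or any MDAnalysis-supported topology) and
    ``trajectory`` an optional coordinate file (PDB/DCD/XTC); without one
    the topology's own frames are used.  Amide hydrogens must be present
    (H/HN/H1 on each non-proline, non-N-terminal residue); residues without
    one are reported and raise.

    Protein acceptors are all protein O atoms plus side-chain N atoms;
    water acceptors are water oxygens.  Returns one series per residue id.
    """
    import MDAnalysis as mda
    args = (str(topology),) if trajectory is None \
        else (str(topology), str(trajectory))
    try:
        u = mda.Universe(*args)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot open trajectory input: {exc}") from exc
    protein = u.select_atoms("protein")
    if protein.n_atoms == 0:
        # topologies without standard residue tagging: everything non-water
        protein = u.select_atoms(
            "not resname " + " ".join(sorted(WATER_RESNAMES)))
    water_o = u.select_atoms(
        "resname " + " ".join(sorted(WATER_RESNAMES))).select_atoms(
        "name O OW OH2")

    donors = []   # (res_id, N index, H index)
    missing = []
    first_resid = int(protein.residues.resids.min()) if protein.n_atoms else 0
    for res in protein.residues:
        if res.resname == "PRO":
            continue
        names = {a.name: a.ix for a in res.atoms}
        n_ix = names.get("N")
        h_ix = next((names[n] for n in ("H", "HN", "H1") if n in names), None)
        if n_ix is None:
            continue
        if h_ix is None:
            if res.resid == first_resid:
                continue   # free amine terminus
            missing.append(int(res.resid))
            continue
        donors.append((int(res.resid), n_ix, h_ix))
    if missing:
        raise ValueError(
            f"missing amide hydrogens (add them or supply a flag CSV) for "
            f"residues {missing}")

    prot_o = protein.select_atoms("name O* OXT")
    sidechain_n = protein.select_atoms("name N* and not name N")
    acceptor_ix = np.concatenate([prot_o.ix, sidechain_n.ix]).astype(int)
    water_ix = water_o.ix.astype(int)

    n_frames = len(range(0, len(u.trajectory), stride))
    prot_flags = {r: np.zeros(n_frames, bool) for r, _, _ in donors}
    water_flags = {r: np.zeros(n_frames, bool) for r, _, _ in donors}
    cos_cut = np.cos(np.deg2rad(theta_cut_deg))
    for fi, _ts in enumerate(u.trajectory[::stride]):
        coords = u.atoms.positions
        for res_id, n_ix, h_ix in donors:
            n_xyz = coords[n_ix]
            h_xyz = coords[h_ix]
            nh = h_xyz - n_xyz
            nh /= np.linalg.norm(nh)
            for flags, acc in ((prot_flags, acceptor_ix),
                               (water_flags, water_ix)):
                if len(acc) == 0:
                    continue
                cand = acc[acc != n_ix]
                vec = coords[cand] - n_xyz
                dist = np.linalg.norm(vec, axis=1)
                near = (dist <= d_cut) & (dist > 1e-6)
                if not near.any():
                    continue
                cosang = (vec[near] @ nh) / dist[near]
                if (cosang >= cos_cut).any():
                    flags[res_id][fi] = True

    return {r: AmideHBondSeries(r, prot_flags[r], water_flags[r])
            for r, _, _ in donors}


def compute_protection(series: dict[int, AmideHBondSeries],
                       params: LogisticParams,
                       mode: str = "protein_not_water") -> ProtectionProfile:
    """Closed fractions and logistic protection factors per residue.

    PF is floored at 1 (a closed fraction can slow exchange, never
    catalyze it below the intrinsic rate).
    """
    n_frames = min(s.n_frames for s in series.values())
    if n_frames < 100:
        logger.warning("only %d frames; closed fractions will be noisy",
                       n_frames)
    x = {r: s.closed_fraction(mode) for r, s in series.items()}
    pf = {r: float(max(1.0, np.exp(params.ln_pf(xi)))) for r, xi in x.items()}
    return ProtectionProfile(closed_fraction=x, pf=pf, params=params,
                             n_frames=n_frames, mode=mode)


def predict_uptake(profile: ProtectionProfile, rates: ResidueRates,
                   timepoints_s) -> pd.DataFrame:
    """Per-residue deuteration D_i(t) under EX2 kinetics.

    Rows indexed by residue, one column per timepoint.  Residues without a
    protection estimate or without an intrinsic rate (residue 1, prolines)
    emit 0.
    """
    t = np.asarray(timepoints_s, dtype=float)
    n = len(rates.sequence)
    d = np.zeros((n, len(t)))
    for res in range(1, n + 1):
        k_min = rates.k_int_per_min[res - 1]
        if not np.isfinite(k_min) or res not in profile.pf:
            continue
        k_s = k_min / 60.0
        d[res - 1] = 1.0 - np.exp(-k_s * t / profile.pf[res])
    return pd.DataFrame(d, index=pd.RangeIndex(1, n + 1, name="residue"),
                        columns=t)


def aggregate_to_peptides(residue_d: pd.DataFrame, peptide_map: list[Peptide],
                          convention: str = "skip_first",
                          state: str = "predicted") -> UptakeTable:
    """Sum per-residue deuteration into a predicted peptide uptake table.

    Uses the same exchanging-residue convention as the simulator and the
    maximum-uptake bookkeeping (peptide N-terminal residue(s) and prolines
    excluded), so predictions are head-to-head comparable with experiment.
    """
    from .synth import _exchanging_positions
    rows = []
    for pep in peptide_map:
        pos = _exchanging_positions(pep.sequence, 1, len(pep.sequence),
                                    convention)
        abs_pos = [pep.start + p - 1 for p in pos]
        for t in residue_d.columns:
            total = float(residue_d.loc[abs_pos, t].sum()) if abs_pos else 0.0
            rows.append({
                "protein": pep.protein_id, "state": state,
                "start": pep.start, "end": pep.end, "sequence": pep.sequence,
                "exposure_s": float(t), "uptake_Da": max(0.0, total),
                "sd_Da": 0.0, "n_reps": 1,
            })
    return UptakeTable(pd.DataFrame(rows, columns=CANONICAL_COLUMNS),
                       {"predicted": True, "convention": convention})


def _predicted_max_uptake(params: LogisticParams,
                          closed_fractions: dict[int, float],
                          rates: ResidueRates, peptide_map: list[Peptide],
                          t_max_s: float, convention: str) -> np.ndarray:
    prof_pf = {r: float(max(1.0, np.exp(params.ln_pf(x))))
               for r, x in closed_fractions.items()}
    profile = ProtectionProfile(closed_fractions, prof_pf, params, 1)
    d = predict_uptake(profile, rates, [t_max_s])
    table = aggregate_to_peptides(d, peptide_map, convention)
    df = table.df.sort_values(["start", "end"])
    return df["uptake_Da"].to_numpy()


def calibrate_logistic(experimental: UptakeTable,
                       series: dict[int, AmideHBondSeries],
                       rates: ResidueRates,
                       mode: str = "protein_not_water",
                       convention: str = "skip_first",
                       grid_size: int = 8,
                       ) -> tuple[LogisticParams, float]:
    """Fit (L, x0, s) by SSE between predicted and experimental maximum
    uptake over the peptide map.

    Experimental maximum uptake is taken at each peptide's largest
    timepoint.  A coarse deterministic grid seeds a bounded local
    optimizer (L in [0, ln 1e9], x0 in [0, 1], s in (0, 100]); a flat SSE
    surface triggers a degenerate-fit warning.  Returns the parameters and
    the final SSE.
    """
    from scipy.optimize import minimize
    peptides = sorted(experimental.peptides(), key=lambda p: p.span)
    if len(peptides) < 5:
        raise ValueError(
            f"need >= 5 peptides with experimental uptake, got {len(peptides)}")
    x_frac = {r: s.closed_fraction(mode) for r, s in series.items()}
    t_max = float(experimental.df["exposure_s"].max())
    obs = np.array([
        experimental.curve(p).set_index("exposure_s")["uptake_Da"].loc[t_max]
        for p in peptides])

    def sse(v):
        L, x0, s = v
        if L <= 0 or s <= 0:
            return 1e12
        pred = _predicted_max_uptake(LogisticParams(L, x0, s), x_frac, rates,
                                     peptides, t_max, convention)
        return float(np.sum((pred - obs) ** 2))

    bounds = [(1e-6, np.log(1e9)), (0.0, 1.0), (1e-3, 100.0)]
    grid_l = np.linspace(np.log(10.0), np.log(1e8), grid_size)
    grid_x0 = np.linspace(0.1, 0.9, grid_size)
    grid_s = np.array([2.0, 5.0, 10.0, 20.0])
    evals = [((L, x0, s), sse((L, x0, s)))
             for L in grid_l for x0 in grid_x0 for s in grid_s]
    evals.sort(key=lambda e: e[1])
    if np.isclose(evals[0][1], evals[-1][1], rtol=1e-6, atol=1e-12):
        logger.warning("flat SSE surface over the parameter grid "
                       "(min %.3g, max %.3g); fit is degenerate",
                       evals[0][1], evals[-1][1])
    best_v, best_f = evals[0]
    for v0, _ in evals[:3]:
        res = minimize(sse, x0=np.asarray(v0), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10,
                                "maxiter": 4000})
        if res.fun < best_f:
            best_v, best_f = res.x, float(res.fun)
    L, x0, s = (float(np.clip(v, lo, hi))
                for v, (lo, hi) in zip(best_v, bounds))
    return LogisticParams(L, x0, s), best_f


def profile_to_dataframe(profile: ProtectionProfile) -> pd.DataFrame:
    res = sorted(profile.pf)
    return pd.DataFrame({
        "residue": res,
        "closed_fraction": [profile.closed_fraction[r] for r in res],
        "pf": [profile.pf[r] for r in res],
        "ln_pf": [float(np.log(profile.pf[r])) for r in res],
    })


def write_flag_csv(series: dict[int, AmideHBondSeries], path) -> None:
    """Persist per-frame flags as CSV (residue, frame, protein_flag,
    water_flag) to decouple downstream stages from trajectory formats."""
    rows = []
    for res in sorted(series):
        s = series[res]
        for f in range(s.n_frames):
            rows.append((res, f, int(s.bonded_to_protein[f]),
                         int(s.bonded_to_water[f])))
    pd.DataFrame(rows, columns=["residue", "frame", "protein_flag",
                                "water_flag"]).to_csv(path, index=False)


def read_flag_csv(path) -> dict[int, AmideHBondSeries]:
    df = pd.read_csv(path)
    needed = {"residue", "frame", "protein_flag", "water_flag"}
    if not needed <= set(df.columns):
        raise ValueError(f"flag CSV missing columns {needed - set(df.columns)}")
    out = {}
    for res, sub in df.groupby("residue"):
        sub = sub.sort_values("frame")
        out[int(res)] = AmideHBondSeries(
            int(res), sub["protein_flag"].to_numpy(bool),
            sub["water_flag"].to_numpy(bool))
    return out
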