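"""Synthetic ground truths and inputs for every pipeline stage.

The generator plants a per-residue protection-factor landscape for two
states (``free`` and ``bound``) that differ only inside specified regions,
draws a pepsin-like overlapping peptide map, and simulates peptide-level
uptake tables under the EX2 deuteration model

    D_i(t) = 1 - exp(-k_int,i * t / PF_i)

with replicate Gaussian noise and a global back-exchange loss.  It also
produces Bernoulli per-frame amide H-bond series with specified closed
fractions and small toy structures, so the H-bond, protection and SASA
stages are testable without trajectories or downloads.

Defaults mirror the labeling conditions of the experiments the package
models: timepoints 0/30/60/120 s, 25 C, buffer read pH 7.9, three
replicates.  All randomness is behind a single integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray

from .io import Peptide, UptakeTable, CANONICAL_COLUMNS
from .rates import intrinsic_rates

DEFAULT_TIMEPOINTS_S = (0.0, 30.0, 60.0, 120.0)
DEFAULT_PH_READ = 7.9
DEFAULT_TEMPERATURE_K = 298.15

_NON_PROLINE = [aa for aa in "ACDEFGHIKLMNQRSTVWY"]


@dataclass
class GroundTruth:
    """Planted per-residue log10 protection factors for two states."""

    sequence: str
    log10_pf: dict[str, np.ndarray]   # state -> array over residues (1-based-1)
    pD: float
    temperature_K: float
    delta_regions: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self):
        for state, arr in self.log10_pf.items():
            if (np.asarray(arr) < 0).any():
                raise ValueError(f"log10 PF < 0 in state {state!r}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def non_exchanging(self) -> list[int]:
        """1-based positions with no backbone amide deuterium (residue 1
        and prolines)."""
        return [i for i in range(1, self.n_residues + 1)
                if i == 1 or self.sequence[i - 1] == "P"]

    def pf(self, state: str) -> np.ndarray:
        return 10.0 ** np.asarray(self.log10_pf[state], dtype=float)

    def to_json(self) -> str:
        return json.dumps({
            "sequence": self.sequence,
            "pD": self.pD,
            "temperature_K": self.temperature_K,
            "delta_regions": [list(r) for r in self.delta_regions],
            "log10_pf": {s: np.asarray(a).tolist()
                         for s, a in self.log10_pf.items()},
        }, indent=1)


def generate_ground_truth(n_residues: int,
                          delta_regions: list[tuple[int, int, float]] = (),
                          base_log10_pf: float = 3.0,
                          seed: int = 0,
                          proline_freq: float = 0.04,
                          jitter: float = 1.0,
                          exposed_regions: list[tuple[int, int]] = (),
                          pH_read: float = DEFAULT_PH_READ,
                          temperature_K: float = DEFAULT_TEMPERATURE_K,
                          ) -> GroundTruth:
    """Draw a sequence and a two-state protection landscape.

    The free state is ``base_log10_pf`` plus uniform per-residue jitter
    (clipped at 0); the bound state applies each region's delta log10 PF on
    top.  The default base of 3 with unit jitter places observed rates
    (k_int / PF) across a 0.5-2 min labeling window.  ``exposed_regions``
    force log10 PF = 0 in both states, emulating the fully exchanged
    reference peptide that back-exchange correction relies on.  Delta
    regions must lie within the sequence and not overlap.
    """
    regions = [tuple(r) for r in delta_regions]
    for start, end, _ in regions:
        if not (1 <= start <= end <= n_residues):
            raise ValueError(f"region {start}-{end} outside 1..{n_residues}")
    for i, (s1, e1, _) in enumerate(regions):
        for s2, e2, _ in regions[i + 1:]:
            if s1 <= e2 and s2 <= e1:
                raise ValueError(
                    f"overlapping delta regions {s1}-{e1} and {s2}-{e2}")
    rng = np.random.default_rng(seed)
    seq = []
    for _ in range(n_residues):
        if rng.random() < proline_freq:
            seq.append("P")
        else:
            seq.append(_NON_PROLINE[rng.integers(len(_NON_PROLINE))])
    sequence = "".join(seq)
    free = np.clip(base_log10_pf
                   + rng.uniform(-jitter, jitter, size=n_residues), 0, None)
    for start, end in (tuple(r) for r in exposed_regions):
        if not (1 <= start <= end <= n_residues):
            raise ValueError(
                f"exposed region {start}-{end} outside 1..{n_residues}")
        free[start - 1:end] = 0.0
    bound = free.copy()
    for start, end, delta in regions:
        bound[start - 1:end] = np.clip(bound[start - 1:end] + delta, 0, None)
    return GroundTruth(sequence=sequence,
                       log10_pf={"free": free, "bound": bound},
                       pD=pH_read + 0.4, temperature_K=temperature_K,
                       delta_regions=regions)


def generate_peptide_map(sequence: str, mean_length: int = 10,
                         mean_overlap: int = 3, seed: int = 0,
                         protein_id: str = "SYN",
                         include_spans: list[tuple[int, int]] = (),
                         ) -> list[Peptide]:
    """Tile the sequence with overlapping peptides, pepsin-map style.

    At least one nested pair sharing a start endpoint is always included,
    so overlap subtraction downstream has work to do.  ``include_spans``
    forces specific peptides into the map (e.g. a back-exchange template
    region).  Coverage is not guaranteed to be complete; callers can
    compute it from the spans.
    """
    n = len(sequence)
    if not 3 <= mean_length <= n:
        raise ValueError("mean_length must be in [3, n_residues]")
    rng = np.random.default_rng(seed)
    spans: list[tuple[int, int]] = []
    start = 1
    while start <= n - 2:
        length = int(np.clip(rng.poisson(mean_length), 3, n - start + 1))
        end = start + length - 1
        spans.append((start, end))
        advance = max(1, length - max(0, int(rng.poisson(mean_overlap))))
        start += advance
    # guarantee a nested, shared-start pair on the longest peptide
    longest = max(spans, key=lambda sp: sp[1] - sp[0])
    if longest[1] - longest[0] + 1 >= 6:
        short = (longest[0], longest[0] + (longest[1] - longest[0]) // 2)
    else:
        short = (longest[0], longest[0] + 2)
    if short not in spans and short[1] - short[0] >= 1:
        spans.append(short)
    for s, e in (tuple(sp) for sp in include_spans):
        if not (1 <= s <= e <= n):
            raise ValueError(f"include span {s}-{e} outside 1..{n}")
        spans.append((s, e))
    spans = sorted(set(spans))
    return [Peptide(protein_id, "map", s, e, sequence[s - 1:e])
            for s, e in spans]


def map_coverage(peptides: list[Peptide], n_residues: int) -> float:
    """Fraction of residues covered by at least one peptide."""
    covered = set()
    for p in peptides:
        covered.update(range(p.start, p.end + 1))
    return len(covered) / n_residues


def _exchanging_positions(sequence: str, start: int, end: int,
                          convention: str = "skip_first") -> list[int]:
    """1-based positions within [start, end] that carry reportable
    deuterium: peptide N-terminal residue(s) and prolines excluded."""
    n_skip = {"skip_first": 1, "skip_first_two": 2}[convention]
    return [i for i in range(start + n_skip, end + 1)
            if sequence[i - 1] != "P"]


def residue_deuteration(truth: GroundTruth, state: str,
                        timepoints_s) -> np.ndarray:
    """Noise-free per-residue D_i(t); rows = residues, cols = timepoints.

    Non-exchanging positions are zero.  Intrinsic rates come from the
    sequence at the truth's pD and temperature.
    """
    rates = intrinsic_rates(truth.sequence, truth.pD, truth.temperature_K,
                            apply_pD_correction=False)
    k_per_s = rates.k_int_per_min / 60.0
    pf = truth.pf(state)
    t = np.asarray(timepoints_s, dtype=float)
    with np.errstate(invalid="ignore"):
        d = 1.0 - np.exp(-np.outer(k_per_s / pf, t))
    d[~np.isfinite(d)] = 0.0
    return d


def simulate_uptake(truth: GroundTruth, peptide_map: list[Peptide],
                    timepoints_s=DEFAULT_TIMEPOINTS_S,
                    noise_sd: float = 0.1, backexchange_frac: float = 0.15,
                    n_reps: int = 3, seed: int = 0,
                    convention: str = "skip_first",
                    ) -> dict[str, UptakeTable]:
    """Simulate one uptake table per state of the ground truth.

    Peptide uptake is the sum of residue deuteration over exchanging
    positions, scaled by (1 - backexchange_frac); each replicate at t > 0
    adds Gaussian noise, and the reported mean (clipped at 0) and SD are
    taken over replicates.  t = 0 rows are the nondeuterated reference
    (exactly 0).  Timepoints must include 0.
    """
    t = np.asarray(timepoints_s, dtype=float)
    if 0.0 not in t:
        raise ValueError("timepoints must include 0 (nondeuterated control)")
    if not 0.0 <= backexchange_frac < 1.0:
        raise ValueError("backexchange_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    import pandas as pd
    out: dict[str, UptakeTable] = {}
    for state in truth.log10_pf:
        d_res = residue_deuteration(truth, state, t)
        rows = []
        for pep in peptide_map:
            pos = _exchanging_positions(truth.sequence, pep.start, pep.end,
                                        convention)
            signal = d_res[[p - 1 for p in pos], :].sum(axis=0) \
                if pos else np.zeros_like(t)
            signal = signal * (1.0 - backexchange_frac)
            for j, tp in enumerate(t):
                if tp == 0.0:
                    mean, sd = 0.0, 0.0
                else:
                    reps = signal[j] + rng.normal(0.0, noise_sd, size=n_reps) \
                        if noise_sd > 0 else np.full(n_reps, signal[j])
                    mean = max(0.0, float(np.mean(reps)))
                    sd = float(np.std(reps, ddof=1)) if n_reps > 1 else 0.0
                rows.append({
                    "protein": pep.protein_id, "state": state,
                    "start": pep.start, "end": pep.end,
                    "sequence": pep.sequence, "exposure_s": float(tp),
                    "uptake_Da": mean, "sd_Da": sd, "n_reps": n_reps,
                })
        df = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)
        out[state] = UptakeTable(df, {
            "synthetic": True, "seed": seed, "noise_sd": noise_sd,
            "backexchange_frac": backexchange_frac,
            "convention": convention,
            "temperature_K": truth.temperature_K, "pD": truth.pD,
        })
    return out


def generate_hbond_series(closed_fractions: dict[int, float],
                          n_frames: int, seed: int = 0):
    """Independent Bernoulli per-frame closed/open series per residue.

    Closed frames are marked protein-H-bonded and not water-H-bonded, open
    frames the reverse, so the empirical closed fraction under the
    ``protein_not_water`` observable converges to the requested fraction.
    Returns a dict residue -> AmideHBondSeries.
    """
    from .hbonds import AmideHBondSeries
    rng = np.random.default_rng(seed)
    series = {}
    for res, frac in closed_fractions.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"closed fraction {frac} outside [0, 1]")
        closed = rng.random(n_frames) < frac
        series[int(res)] = AmideHBondSeries(
            residue=int(res), bonded_to_protein=closed,
            bonded_to_water=~closed)
    return series


def generate_toy_structure(kind: str, **params) -> AtomArray:
    """Small deterministic PDB-ready structures for geometry tests.

    ``two_spheres``: two carbon atoms at distance ``d`` (Angstrom).
    ``ideal_helix``: poly-alanine alpha-helix backbone of ``n`` residues on
    an idealized cylindrical parametrization (1.5 A rise, 100 deg turn).
    """
    if kind == "two_spheres":
        d = float(params.get("d", 10.0))
        element = params.get("element", "C")
        arr = AtomArray(2)
        arr.coord = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        for i in range(2):
            arr.chain_id[i] = "A"
            arr.res_id[i] = i + 1
            arr.res_name[i] = "SPH"
            arr.atom_name[i] = element
            arr.element[i] = element
            arr.hetero[i] = True
        return arr
    if kind == "ideal_helix":
        n = int(params.get("n", 12))
        # (atom, element, radius A, phase offset deg, z offset A)
        geom = [("N", "N", 1.55, -28.0, -0.70),
                ("H", "H", 1.55, -28.0, -1.70),
                ("CA", "C", 2.28, 0.0, 0.00),
                ("C", "C", 1.67, 27.0, 0.74),
                ("O", "O", 2.04, 49.0, 0.90)]
        arr = AtomArray(n * len(geom))
        idx = 0
        for res in range(n):
            base_ang = np.deg2rad(100.0 * res)
            base_z = 1.5 * res
            for name, elem, r, dphi, dz in geom:
                ang = base_ang + np.deg2rad(dphi)
                arr.coord[idx] = [r * np.cos(ang), r * np.sin(ang),
                                  base_z + dz]
                arr.chain_id[idx] = "A"
                arr.res_id[idx] = res + 1
                arr.res_name[idx] = "ALA"
                arr.atom_name[idx] = name
                arr.element[idx] = elem
                idx += 1
        return arr
    raise ValueError(f"unknown toy structure kind {kind!r}")


def write_structure_pdb(arr: AtomArray, path) -> None:
    from biotite.structure.io.pdb import PDBFile
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))
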