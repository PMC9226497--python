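"""End-to-end drivers for the two workflows.

``run_differential`` chains the experimental analysis: read free/bound
tables (or simulate them), correct back-exchange, fit single exponentials,
subtract overlapping peptides, difference the fitted maximum uptakes and
classify significance, optionally painting per-residue differences onto a
structure's B-factors.

``run_predict`` chains the structure/MD route: per-frame amide H-bond
flags (from a trajectory or a precomputed flag CSV) -> closed fractions ->
logistic protection factors -> intrinsic-rate-weighted deuteration ->
peptide aggregation -> correlation against an experimental table.

Both take a flat config mapping (YAML-friendly); unknown keys are
rejected, every effective value is echoed into the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import hbonds as hb
from . import kinetics as kin
from . import peptides as pops
from . import synth
from .io import ResidueMap, read_state_table, write_residue_map_pdb
from .rates import intrinsic_rates

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


DIFFERENTIAL_KEYS = {
    "free_table", "bound_table", "dialect", "simulate", "backexchange",
    "sigma_multiplier", "min_delta", "m", "convention", "outdir",
    "structure", "free_state", "bound_state", "seed",
}
PREDICT_KEYS = {
    "sequence", "flags_csv", "topology", "trajectory", "stride",
    "logistic", "calibrate", "experimental_table", "dialect",
    "pH_read", "temperature_K", "timepoints_s", "mode", "convention",
    "outdir", "seed",
}


def _check_keys(config: dict, allowed: set, which: str) -> None:
    unknown = set(config) - allowed
    if unknown:
        raise StageError("config", f"unknown {which} keys: {sorted(unknown)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(outdir: Path, config: dict, inputs: list[Path]) -> None:
    manifest = {
        "config": {k: (str(v) if isinstance(v, Path) else v)
                   for k, v in config.items()},
        "inputs": {str(p): _sha256(p) for p in inputs if p and p.exists()},
    }
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))


def run_differential(config: dict) -> dict:
    """Run the differential-uptake workflow; returns the report bundle."""
    _check_keys(config, DIFFERENTIAL_KEYS, "differential")
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    convention = config.get("convention", "skip_first")
    free_state = config.get("free_state", "free")
    bound_state = config.get("bound_state", "bound")
    inputs: list[Path] = []

    # -- read or simulate --------------------------------------------------
    if "simulate" in config:
        sim = dict(config["simulate"])
        truth = synth.generate_ground_truth(
            n_residues=sim.get("n_residues", 60),
            delta_regions=sim.get("delta_regions", []),
            base_log10_pf=sim.get("base_log10_pf", 3.0),
            exposed_regions=sim.get("exposed_regions", []),
            seed=sim.get("seed", config.get("seed", 0)))
        include = []
        if "backexchange" in config:
            include.append(tuple(config["backexchange"]["template"]))
        pep_map = synth.generate_peptide_map(
            truth.sequence, seed=sim.get("seed", config.get("seed", 0)),
            include_spans=include)
        tables = synth.simulate_uptake(
            truth, pep_map,
            noise_sd=sim.get("noise_sd", 0.1),
            backexchange_frac=sim.get("backexchange_frac", 0.15),
            n_reps=sim.get("n_reps", 3),
            seed=sim.get("seed", config.get("seed", 0)),
            convention=convention)
        free, bound = tables["free"], tables["bound"]
        (outdir / "ground_truth.json").write_text(truth.to_json())
    else:
        dialect = config.get("dialect", "canonical")
        try:
            free_path = Path(config["free_table"])
            free = read_state_table(free_path, dialect)
            inputs.append(free_path)
        except KeyError:
            raise StageError("read", "free_table not configured")
        except (OSError, ValueError) as exc:
            raise StageError("read", f"free table: {exc}")
        try:
            bound_path = Path(config["bound_table"])
            bound = read_state_table(bound_path, dialect)
            inputs.append(bound_path)
        except KeyError:
            raise StageError("read", "bound_table not configured")
        except (OSError, ValueError) as exc:
            raise StageError("read", f"bound table: {exc}")

    # -- back-exchange correction -----------------------------------------
    be_fracs = {}
    if "backexchange" in config:
        be = dict(config["backexchange"])
        span = tuple(be["template"])
        try:
            res_free = pops.correct_backexchange(
                free, span, plateau=be.get("plateau", "last_timepoint"),
                convention=convention, template_state=be.get("state"))
            res_bound = pops.correct_backexchange(
                bound, span, plateau=be.get("plateau", "last_timepoint"),
                convention=convention, template_state=be.get("state"))
        except ValueError as exc:
            raise StageError("backexchange", str(exc))
        free, bound = res_free.corrected, res_bound.corrected
        be_fracs = {"free": res_free.be_frac, "bound": res_bound.be_frac}

    # -- fits --------------------------------------------------------------
    for state, table in (("free", free), ("bound", bound)):
        wanted = free_state if state == "free" else bound_state
        if wanted not in table.states():
            raise StageError("fit", f"state not found: {wanted!r} "
                                    f"(table has {table.states()})")
    try:
        free_fits = kin.fit_table(free.select(state=free_state), convention)
        bound_fits = kin.fit_table(bound.select(state=bound_state), convention)
    except ValueError as exc:
        raise StageError("fit", str(exc))

    # -- overlap subtraction ----------------------------------------------
    sigma_mult = config.get("sigma_multiplier", 5.0)
    overhangs = (pops.subtract_overlaps(free.select(state=free_state),
                                        sigma_mult)
                 + pops.subtract_overlaps(bound.select(state=bound_state),
                                          sigma_mult))

    # -- differential calls ------------------------------------------------
    calls = kin.differential_calls(
        free_fits, bound_fits,
        min_delta=config.get("min_delta", 0.5), m=config.get("m", 2.0))

    # -- outputs -----------------------------------------------------------
    kin.fits_to_dataframe(free_fits + bound_fits).to_csv(
        outdir / "fits.csv", index=False)
    kin.calls_to_dataframe(calls).to_csv(outdir / "calls.csv", index=False)
    pops.overhangs_to_dataframe(overhangs).to_csv(
        outdir / "overhangs.csv", index=False)
    (outdir / "woods.txt").write_text(kin.woods_report(calls))
    kin.woods_plot(calls, outdir / "woods.png",
                   min_delta=config.get("min_delta", 0.5))
    if "structure" in config:
        residue_values: dict[int, float] = {}
        for c in calls:
            if c.cls == "not_significant":
                continue
            for r in range(c.peptide.start, c.peptide.end + 1):
                residue_values[r] = c.delta_D
        rmap = ResidueMap(calls[0].peptide.protein_id if calls else "",
                          residue_values)
        write_residue_map_pdb(config["structure"], rmap,
                              outdir / "delta_map.pdb")
        inputs.append(Path(config["structure"]))
    _manifest(outdir, config, inputs)
    return {"free_fits": free_fits, "bound_fits": bound_fits,
            "calls": calls, "overhangs": overhangs,
            "backexchange": be_fracs, "outdir": outdir}


def run_predict(config: dict) -> dict:
    """Run the MD-based prediction workflow; returns the report bundle."""
    _check_keys(config, PREDICT_KEYS, "predict")
    outdir = Path(config.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    convention = config.get("convention", "skip_first")
    mode = config.get("mode", "protein_not_water")
    timepoints = config.get("timepoints_s", list(synth.DEFAULT_TIMEPOINTS_S))
    inputs: list[Path] = []

    sequence = config.get("sequence")
    if sequence and Path(str(sequence)).exists():
        path = Path(sequence)
        inputs.append(path)
        text = path.read_text().splitlines()
        sequence = "".join(l.strip() for l in text if not l.startswith(">"))
    if not sequence:
        raise StageError("rates", "sequence not configured")

    # -- H-bond series -----------------------------------------------------
    if "flags_csv" in config:
        try:
            series = hb.read_flag_csv(config["flags_csv"])
            inputs.append(Path(config["flags_csv"]))
        except (OSError, ValueError) as exc:
            raise StageError("hbonds", f"cannot open: {exc}")
    elif "topology" in config:
        try:
            series = hb.classify_hbonds(config["topology"],
                                        config.get("trajectory"),
                                        stride=config.get("stride", 1))
        except (OSError, ValueError) as exc:
            raise StageError("hbonds", f"cannot open: {exc}")
        inputs.append(Path(config["topology"]))
    else:
        raise StageError("hbonds", "need flags_csv or topology")

    # -- rates -------------------------------------------------------------
    try:
        rates = intrinsic_rates(sequence,
                                config.get("pH_read", synth.DEFAULT_PH_READ),
                                config.get("temperature_K",
                                           synth.DEFAULT_TEMPERATURE_K))
    except ValueError as exc:
        raise StageError("rates", str(exc))

    experimental = None
    if "experimental_table" in config:
        try:
            experimental = read_state_table(
                config["experimental_table"],
                config.get("dialect", "canonical"))
            inputs.append(Path(config["experimental_table"]))
        except (OSError, ValueError) as exc:
            raise StageError("read", str(exc))

    # -- protection --------------------------------------------------------
    if config.get("calibrate"):
        if experimental is None:
            raise StageError("protection",
                             "calibrate requested without experimental_table")
        params, sse = hb.calibrate_logistic(experimental, series, rates,
                                            mode=mode, convention=convention)
        logger.info("calibrated logistic params L=%.3f x0=%.3f s=%.3f "
                    "(SSE %.4g)", params.L, params.x0, params.s, sse)
    else:
        lg = dict(config.get("logistic", {}))
        params = hb.LogisticParams(lg.get("L", np.log(1e6)),
                                   lg.get("x0", 0.5), lg.get("s", 10.0))
    profile = hb.compute_protection(series, params, mode)

    # -- predict and aggregate --------------------------------------------
    residue_d = hb.predict_uptake(profile, rates, timepoints)
    if experimental is not None:
        pep_map = experimental.peptides()
    else:
        pep_map = synth.generate_peptide_map(sequence,
                                             seed=config.get("seed", 0))
    predicted = hb.aggregate_to_peptides(residue_d, pep_map, convention)

    # -- correlate ---------------------------------------------------------
    corr = None
    if experimental is not None:
        from .sasa import correlate
        t_max = float(experimental.df["exposure_s"].max())
        pairs = []
        pred_df = predicted.df.set_index(["start", "end"])
        for p in experimental.peptides():
            curve = experimental.curve(p).set_index("exposure_s")
            if t_max in curve.index and (p.start, p.end) in pred_df.index:
                prow = pred_df.loc[(p.start, p.end)]
                prow = prow[prow["exposure_s"] == t_max]
                pairs.append((float(prow["uptake_Da"].iloc[0]),
                              float(curve.loc[t_max, "uptake_Da"]),
                              f"{p.start}-{p.end}"))
        if len(pairs) >= 3:
            corr = correlate([p[0] for p in pairs], [p[1] for p in pairs],
                             ids=[p[2] for p in pairs])
        else:
            logger.info("fewer than 3 comparable peptides; correlation "
                        "skipped")
    else:
        logger.info("no experimental table given; correlation skipped")

    hb.profile_to_dataframe(profile).to_csv(outdir / "protection.csv",
                                            index=False)
    predicted.write_csv(outdir / "predicted_uptake.csv")
    if corr is not None:
        (outdir / "correlation.json").write_text(json.dumps({
            "n": corr.n, "r": corr.r, "r2": corr.r2,
            "slope": corr.slope, "intercept": corr.intercept}, indent=1))
    _manifest(outdir, config, inputs)
    return {"params": params, "profile": profile, "predicted": predicted,
            "correlation": corr, "outdir": outdir}
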