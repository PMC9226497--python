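"""Back-exchange correction and overlapping-peptide subtraction.

Back-exchange (loss of label during quench and chromatography) is corrected
against a template peptide assumed fully exchanged at plateau: the observed
plateau uptake over the template's theoretical maximum gives the retained
fraction, and every uptake (and SD) in the table is divided by it.

Spatial resolution beyond the peptide level uses nested peptide pairs that
share exactly one endpoint: the uptake of the overhanging region is the
difference of the two peptide uptakes, with SDs propagated in quadrature,
and is accepted when the difference exceeds ``sigma_multiplier`` (default 5)
times its propagated uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Peptide, UptakeTable

logger = logging.getLogger(__name__)


def exchangeable_amides(peptide: Peptide | str,
                        convention: str = "skip_first") -> int:
    """Number of backbone amides of a peptide that can retain deuterium.

    The first one or two N-terminal residues are excluded (their label is
    assumed lost during analysis; ``skip_first`` is the DynamX-style
    default) along with every proline at a non-skipped position.
    """
    seq = peptide.sequence if isinstance(peptide, Peptide) else peptide
    n_skip = {"skip_first": 1, "skip_first_two": 2}[convention]
    return sum(1 for aa in seq[n_skip:] if aa != "P")


@dataclass
class BackExchangeResult:
    template: Peptide
    be_frac: float
    corrected: UptakeTable
    template_plateau_Da: float
    template_max_Da: int


def correct_backexchange(table: UptakeTable, template_span: tuple[int, int],
                         plateau: str = "last_timepoint",
                         convention: str = "skip_first",
                         template_state: str | None = None,
                         ) -> BackExchangeResult:
    """Correct every uptake in ``table`` using a fully-exchanged template.

    ``template_span`` is the (start, end) of the template peptide;
    ``template_state`` selects the state it is taken from when the table
    holds several (the template may come from a different state than the
    rows being corrected, e.g. a bound-state peptide correcting the whole
    experiment).  ``plateau`` is the template's uptake at the largest
    timepoint (default) or the plateau of a single-exponential fit.
    """
    df = table.df
    m = (df["start"] == template_span[0]) & (df["end"] == template_span[1])
    if template_state is not None:
        m &= df["state"] == template_state
    sub = df.loc[m]
    if sub.empty:
        raise ValueError(f"template peptide {template_span} not found in table")
    sub_nz = sub[sub["exposure_s"] > 0]
    if sub_nz.empty:
        raise ValueError("template peptide has no nonzero timepoint")
    row = sub_nz.loc[sub_nz["exposure_s"].idxmax()]
    template = Peptide(row["protein"], row["state"], int(row["start"]),
                       int(row["end"]), row["sequence"])
    n_exch = exchangeable_amides(template, convention)
    if plateau == "last_timepoint":
        plateau_Da = float(row["uptake_Da"])
    elif plateau == "fitted":
        from .kinetics import fit_exponential
        plateau_Da = fit_exponential(table, template).A
    else:
        raise ValueError(f"unknown plateau mode {plateau!r}")
    be_frac = 1.0 - plateau_Da / n_exch
    if -1e-9 < be_frac < 0:    # exactly-at-max template, rounding only
        be_frac = 0.0
    if be_frac < 0:
        raise ValueError(
            f"template uptake {plateau_Da:.3f} Da exceeds its theoretical "
            f"maximum of {n_exch} (ratio {plateau_Da / n_exch:.3f}); not a "
            f"valid fully-exchanged template")
    factor = 1.0 / (1.0 - be_frac)
    out = df.copy()
    out["uptake_Da"] = out["uptake_Da"] * factor
    out["sd_Da"] = out["sd_Da"] * factor
    meta = dict(table.metadata)
    meta["backexchange_corrected"] = True
    meta["backexchange_frac"] = be_frac
    meta["backexchange_template"] = f"{template_span[0]}-{template_span[1]}"
    corrected = UptakeTable(out, meta)
    return BackExchangeResult(template, be_frac, corrected, plateau_Da, n_exch)


@dataclass
class OverhangMeasurement:
    """Uptake of the region by which a longer peptide overhangs a nested
    shorter one, from subtraction of their uptakes at one timepoint."""

    region: tuple[int, int]
    parent_long: Peptide
    parent_short: Peptide
    exposure_s: float
    uptake_Da: float
    sd_Da: float
    accepted: bool


def _nested_pairs(peptides: list[Peptide]):
    """Yield (long, short) pairs where short is strictly inside long and
    they share exactly one endpoint (contiguous overhang)."""
    for p_long in peptides:
        for p_short in peptides:
            if p_long.span == p_short.span:
                continue
            if not (p_long.start <= p_short.start
                    and p_short.end <= p_long.end):
                continue
            shares_start = p_long.start == p_short.start
            shares_end = p_long.end == p_short.end
            if shares_start == shares_end:   # neither or both endpoints
                continue
            yield p_long, p_short


def subtract_overlaps(table: UptakeTable, sigma_multiplier: float = 5.0,
                      ) -> list[OverhangMeasurement]:
    """Overhang uptakes from all qualifying nested peptide pairs.

    Operates per (protein, state) group; one measurement per pair per
    shared timepoint.  The acceptance flag applies the m-sigma rule
    (|difference| > sigma_multiplier x propagated SD).  Identical spans are
    skipped (zero-length overhang).
    """
    results: list[OverhangMeasurement] = []
    for (_, _), sub in table.df.groupby(["protein", "state"]):
        sub_table = UptakeTable(sub, table.metadata)
        peptides = sub_table.peptides()
        for p_long, p_short in _nested_pairs(peptides):
            if p_long.start == p_short.start:
                region = (p_short.end + 1, p_long.end)
            else:
                region = (p_long.start, p_short.start - 1)
            c_long = sub_table.curve(p_long).set_index("exposure_s")
            c_short = sub_table.curve(p_short).set_index("exposure_s")
            shared_t = sorted(set(c_long.index) & set(c_short.index))
            for t in shared_t:
                d = float(c_long.loc[t, "uptake_Da"]
                          - c_short.loc[t, "uptake_Da"])
                sd = float(np.hypot(c_long.loc[t, "sd_Da"],
                                    c_short.loc[t, "sd_Da"]))
                results.append(OverhangMeasurement(
                    region=region, parent_long=p_long, parent_short=p_short,
                    exposure_s=float(t), uptake_Da=d, sd_Da=sd,
                    accepted=bool(abs(d) > sigma_multiplier * sd)))
    return results


def overhangs_to_dataframe(overhangs: list[OverhangMeasurement]) -> pd.DataFrame:
    rows = []
    for o in overhangs:
        rows.append({
            "protein": o.parent_long.protein_id,
            "state": o.parent_long.state,
            "region_start": o.region[0],
            "region_end": o.region[1],
            "parent_long": f"{o.parent_long.start}-{o.parent_long.end}",
            "parent_short": f"{o.parent_short.start}-{o.parent_short.end}",
            "exposure_s": o.exposure_s,
            "uptake_Da": o.uptake_Da,
            "sd_Da": o.sd_Da,
            "accepted": o.accepted,
        })
    return pd.DataFrame(rows)
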