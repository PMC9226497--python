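"""Independent brute-force / closed-form oracles used by the test suite.

Every function here is deliberately written in the most literal style
possible (plain loops over plain dict literals, no shared code with the
package) so that agreement with the package implementation is a meaningful
cross-check rather than a tautology.
"""

import math

# ---------------------------------------------------------------------------
# Intrinsic exchange-rate oracle: a spreadsheet-style transcription of the
# poly-DL-alanine reference chemistry (D2O).  Literal tables, scalar loops.
# ---------------------------------------------------------------------------

# residue: (acid_lambda, acid_rho, base_lambda, base_rho), log10
_ORACLE_FACTORS = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D": (0.90, 0.58, -0.30, -0.18),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "E": (-0.90, 0.31, -0.51, -0.15),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "H": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}


def oracle_kint(sequence, pD, temperature_K):
    """Per-residue intrinsic rates in min^-1 (None for non-exchanging)."""
    n = len(sequence)
    out = []
    for i in range(1, n + 1):
        aa = sequence[i - 1]
        if i == 1 or aa == "P":
            out.append(None)
            continue
        prev = sequence[i - 2]
        fa = _ORACLE_FACTORS[aa][0] + _ORACLE_FACTORS[prev][1]
        fb = _ORACLE_FACTORS[aa][2] + _ORACLE_FACTORS[prev][3]
        if i == 2:
            fa = fa + (-1.32)
            fb = fb + 1.62
        if i == n:
            fa = fa + 0.96
            fb = fb + (-1.80)
        # reference log10 constants at 293 K, D2O
        ka = 10.0 ** (1.62 + fa) * 10.0 ** (-pD)
        kb = 10.0 ** (10.05 + fb) * 10.0 ** (pD - 15.05)
        kw = 10.0 ** (-1.50 + fb)
        R = 1.987204e-3
        ka *= math.exp(-14.0 / R * (1.0 / temperature_K - 1.0 / 293.0))
        kb *= math.exp(-17.0 / R * (1.0 / temperature_K - 1.0 / 293.0))
        kw *= math.exp(-19.0 / R * (1.0 / temperature_K - 1.0 / 293.0))
        out.append(ka + kb + kw)
    return out


# ---------------------------------------------------------------------------
# Overlap-subtraction oracle: enumerate ALL ordered peptide pairs, apply the
# nesting / shared-endpoint rule and the m-sigma acceptance literally.
# ---------------------------------------------------------------------------

def oracle_overhangs(rows, sigma_multiplier=5.0):
    """rows: list of dicts with protein,state,start,end,exposure_s,
    uptake_Da,sd_Da.  Returns a set of result tuples for exact comparison:
    (protein, state, region, long_span, short_span, t, round(d,9),
     round(sd,9), accepted)."""
    results = set()
    spans = {}
    for r in rows:
        key = (r["protein"], r["state"])
        spans.setdefault(key, set()).add((r["start"], r["end"]))
    by_key = {}
    for r in rows:
        by_key[(r["protein"], r["state"], r["start"], r["end"],
                r["exposure_s"])] = r
    for (prot, state), span_set in spans.items():
        for long_span in span_set:
            for short_span in span_set:
                if long_span == short_span:
                    continue
                ls, le = long_span
                ss, se = short_span
                if not (ls <= ss and se <= le):
                    continue
                if (ls == ss) == (le == se):
                    continue
                if ls == ss:
                    region = (se + 1, le)
                else:
                    region = (ls, ss - 1)
                times = set()
                for r in rows:
                    if (r["protein"], r["state"]) == (prot, state):
                        if (r["start"], r["end"]) in (long_span, short_span):
                            times.add(r["exposure_s"])
                for t in times:
                    rl = by_key.get((prot, state, ls, le, t))
                    rs = by_key.get((prot, state, ss, se, t))
                    if rl is None or rs is None:
                        continue
                    d = rl["uptake_Da"] - rs["uptake_Da"]
                    sd = math.sqrt(rl["sd_Da"] ** 2 + rs["sd_Da"] ** 2)
                    accepted = abs(d) > sigma_multiplier * sd
                    results.add((prot, state, region, long_span, short_span,
                                 t, round(d, 9), round(sd, 9), accepted))
    return results


# ---------------------------------------------------------------------------
# Exponential-fit oracle: dense (A, k) grid minimizing weighted SSE.
# ---------------------------------------------------------------------------

def oracle_grid_fit(t, y, sd, a_max, n_a=200, n_k=200, k_max=1.0):
    """Best (A, k) on a dense grid by weighted SSE; returns (A, k)."""
    best = (None, None, float("inf"))
    for ia in range(1, n_a + 1):
        A = a_max * ia / n_a
        for ik in range(1, n_k + 1):
            k = k_max * ik / n_k
            sse = 0.0
            for ti, yi, si in zip(t, y, sd):
                w = 1.0 / (si * si) if si > 0 else 1.0
                r = yi - A * (1.0 - math.exp(-k * ti))
                sse += w * r * r
            if sse < best[2]:
                best = (A, k, sse)
    return best[0], best[1]


# ---------------------------------------------------------------------------
# Two overlapping spheres: analytic accessible area via spherical caps.
# ---------------------------------------------------------------------------

def oracle_two_sphere_area(r1, r2, d):
    """Accessible (non-buried) area of each of two spheres of radius r1, r2
    with centers d apart.  Valid for partially overlapping spheres."""
    if d >= r1 + r2:
        return 4 * math.pi * r1 ** 2, 4 * math.pi * r2 ** 2
    x1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    h1 = r1 - x1
    h2 = r2 - (d - x1)
    a1 = 4 * math.pi * r1 ** 2 - 2 * math.pi * r1 * h1
    a2 = 4 * math.pi * r2 ** 2 - 2 * math.pi * r2 * h2
    return a1, a2


# ---------------------------------------------------------------------------
# H-bond classification oracle: all-pairs distance/angle scan, plain loops.
# ---------------------------------------------------------------------------

def oracle_hbond_flags(n_xyz, h_xyz, acceptor_xyz, d_cut=3.5, theta_cut=30.0):
    """True if ANY acceptor satisfies N...acc <= d_cut and the angle between
    N->H and N->acc is <= theta_cut degrees."""
    for acc in acceptor_xyz:
        dx = [acc[j] - n_xyz[j] for j in range(3)]
        dist = math.sqrt(sum(v * v for v in dx))
        if dist > d_cut or dist < 1e-6:
            continue
        nh = [h_xyz[j] - n_xyz[j] for j in range(3)]
        nh_len = math.sqrt(sum(v * v for v in nh))
        cosang = sum(dx[j] * nh[j] for j in range(3)) / (dist * nh_len)
        cosang = max(-1.0, min(1.0, cosang))
        if math.degrees(math.acos(cosang)) <= theta_cut:
            return True
    return False


# ---------------------------------------------------------------------------
# Direct per-residue deuteration summation (EX2), scalar loops.
# ---------------------------------------------------------------------------

def oracle_peptide_uptake(sequence, start, end, t_s, kint_per_min, pf,
                          backexchange=0.0, skip=1):
    """Sum 1-exp(-k t / PF) over exchanging residues of [start, end]."""
    total = 0.0
    for i in range(start + skip, end + 1):
        if sequence[i - 1] == "P":
            continue
        k = kint_per_min[i - 1]
        if k is None:
            continue
        total += 1.0 - math.exp(-(k / 60.0) * t_s / pf[i - 1])
    return total * (1.0 - backexchange)
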