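"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain Python loops over per-cell
dictionaries (no pandas, no vectorisation) so it shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.optimize

PCTS = {"01": 1, "25": 25, "50": 50, "75": 75, "99": 99}


def percentile(values, p):
    """Linear interpolation between order statistics."""
    v = sorted(values)
    if not v:
        return math.nan
    h = (p / 100.0) * (len(v) - 1)
    lo = int(math.floor(h))
    if lo + 1 >= len(v):
        return float(v[-1])
    return float(v[lo] + (h - lo) * (v[lo + 1] - v[lo]))


def mean(values):
    values = list(values)
    return sum(values) / len(values) if values else math.nan


def oracle_labels(cells, method="mork"):
    """Per-cell EW/LW labels; cells is a list of dicts."""
    labels = {}
    for c in cells:
        if method == "mork":
            single_rad = (c["cwt_le"] + c["cwt_ri"]) / 2.0
            lw = 4.0 * single_rad / c["drad_lumen"] >= 1.0
        else:
            lw = c["drad_lumen"] / c["dtan_lumen"] < 1.0
        labels[(c["file_index"], c["cell_index"])] = "LW" if lw else "EW"
    return labels


def oracle_ring_traits(cells, *, strip_mm=1.0, eta=1.002e-9,
                       water_density=998.2, method="mork",
                       inner_radius_um=None):
    """Every catalogue trait for one ring, by direct per-cell loops."""
    labels = oracle_labels(cells, method)
    files = sorted({c["file_index"] for c in cells})
    by_file = {f: sorted((c for c in cells if c["file_index"] == f),
                         key=lambda c: c["cell_index"]) for f in files}

    def extent(c):
        return c["drad_lumen"] + c["cwt_le"] + c["cwt_ri"]

    def is_ew(c):
        return labels[(c["file_index"], c["cell_index"])] == "EW"

    # widths
    trw = mean(sum(extent(c) for c in by_file[f]) for f in files)
    eww = mean(sum(extent(c) for c in by_file[f] if is_ew(c)) for f in files)
    lww = trw - eww
    ew_pct = 100.0 * eww / trw
    lw_pct = 100.0 * lww / trw
    out = {"TRW": trw, "EWW": eww, "LWW": lww, "EW%": ew_pct, "LW%": lw_pct,
           "LW%/EW%": lw_pct / ew_pct if ew_pct > 0 else math.nan}

    # counts
    cno = len(cells)
    cno_ew = sum(1 for c in cells if is_ew(c))
    cno_lw = cno - cno_ew
    lw_files = len({c["file_index"] for c in cells if not is_ew(c)})
    n_tang = lw_files / strip_mm
    out.update({
        "CNO": float(cno), "CNO_EW": float(cno_ew), "CNO_LW": float(cno_lw),
        "NoCells_tang": n_tang, "NoCells_rad": cno / n_tang,
        "EW_Nocells": cno_ew / n_tang, "LW_Nocells": cno_lw / n_tang,
        "CD": cno / ((trw / 1000.0) * strip_mm),
    })

    # per-cell wall / lumen quantities
    quantities = {"CWTall": [], "CWTtan": [], "CWTrad": [], "rTSR": [],
                  "RWD": [], "LA": []}
    ew_flags = []
    tb2s, dh_num, dh_den, kh, cwa_sum = [], 0.0, 0.0, 0.0, 0.0
    drads, dtans, cwas = [], [], []
    for c in cells:
        ct = (c["cwt_pi"] + c["cwt_ba"]) / 2.0
        cr = (c["cwt_le"] + c["cwt_ri"]) / 2.0
        quantities["CWTtan"].append(ct)
        quantities["CWTrad"].append(cr)
        quantities["CWTall"].append((ct + cr) / 2.0)
        quantities["rTSR"].append(4.0 * cr / c["drad_lumen"])
        quantities["RWD"].append(c["cwa"] / (c["cwa"] + c["lumen_area"]))
        quantities["LA"].append(c["lumen_area"])
        tb = min(2.0 * cr / c["drad_lumen"], 2.0 * ct / c["dtan_lumen"])
        tb2s.append(tb * tb)
        d = 2.0 * math.sqrt(c["lumen_area"] / math.pi)
        dh_num += d ** 5
        dh_den += d ** 4
        a = c["drad_lumen"] / 2.0 * 1e-6
        b = c["dtan_lumen"] / 2.0 * 1e-6
        kh += math.pi * a ** 3 * b ** 3 / (4.0 * eta * (a * a + b * b))
        cwa_sum += c["cwa"]
        drads.append(c["drad_lumen"])
        dtans.append(c["dtan_lumen"])
        cwas.append(c["cwa"])
        ew_flags.append(is_ew(c))

    for name, vals in quantities.items():
        if name != "LA":
            out[name] = mean(vals)
            out[f"{name}_EW"] = mean(v for v, e in zip(vals, ew_flags) if e)
            out[f"{name}_LW"] = mean(v for v, e in zip(vals, ew_flags) if not e)
        for suffix, p in PCTS.items():
            out[f"{name}_{suffix}"] = percentile(vals, p)
    out["LA"] = mean(quantities["LA"])
    out["Drad"] = mean(drads)
    out["Dtan"] = mean(dtans)
    out["Drad_EW"] = mean(v for v, e in zip(drads, ew_flags) if e)
    out["Dtan_LW"] = mean(v for v, e in zip(dtans, ew_flags) if not e)
    out["CWA"] = mean(cwas)
    out["CWA_EW"] = mean(v for v, e in zip(cwas, ew_flags) if e)
    out["CWA_LW"] = mean(v for v, e in zip(cwas, ew_flags) if not e)
    out["tb2"] = mean(tb2s)
    out["tb2_05"] = percentile(tb2s, 5)
    out["Dh"] = dh_num / dh_den
    out["Kh"] = kh
    out["Ks"] = kh / ((trw * 1e-6) * (strip_mm * 1e-3))
    out["HCUE"] = kh * water_density / cwa_sum
    if inner_radius_um is None:
        out["BAI"] = math.nan
    else:
        r1 = inner_radius_um + trw
        out["BAI"] = math.pi * (r1 ** 2 - inner_radius_um ** 2) / 1e6
    return out


def procrustes_r_numeric(x, y):
    """Procrustes correlation by numeric search over planar rotations.

    Centers and unit-scales both 2-column configurations, then maximises the
    inner product over rotation angle (with and without reflection) using a
    dense grid plus local refinement.
    """
    def norm(z):
        z = z - z.mean(axis=0)
        return z / math.sqrt((z ** 2).sum())

    x, y = norm(np.asarray(x, float)), norm(np.asarray(y, float))

    def fit(theta, reflect):
        c, s = math.cos(theta), math.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        yy = y.copy()
        if reflect:
            yy[:, 1] *= -1.0
        return float((x * (yy @ rot.T)).sum())

    best = -np.inf
    for reflect in (False, True):
        grid = np.linspace(0.0, 2.0 * math.pi, 721)
        vals = [fit(t, reflect) for t in grid]
        t0 = grid[int(np.argmax(vals))]
        res = scipy.optimize.minimize_scalar(
            lambda t: -fit(t, reflect),
            bounds=(t0 - 0.02, t0 + 0.02), method="bounded",
            options={"xatol": 1e-12})
        best = max(best, -res.fun, max(vals))
    return min(best, 1.0)
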