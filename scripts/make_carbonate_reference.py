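"""Generate the frozen carbonate-chemistry reference lattice.

Independently coded scalar evaluator (plain ``math`` + interval bisection,
no shared code with the package solver) for the same published constant set:
Lueker et al. (2000) K1/K2, Dickson (1990a) bisulfate, Dickson & Riley (1979)
fluoride, Uppström (1974) boron, Millero (1995) water/phosphate/silicate and
pressure corrections, Weiss (1974) K0, Mucci (1983) aragonite Ksp.
Writes tests/data/carbonate_reference.csv.

Run from the repository root:  python scripts/make_carbonate_reference.py
"""

import csv
import math
import os

R = 83.1451  # cm3 bar / (mol K)


def constants(tc, s, p_dbar):
    t = tc + 273.15
    pb = p_dbar / 10.0
    lnt = math.log(t)
    s_sq = math.sqrt(s)
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    ion_sq = math.sqrt(ion)

    tb = 0.0004157 * s / 35.0
    ts = 0.14 / 96.062 * s / 1.80655
    tf = 0.000067 / 18.998 * s / 1.80655
    ca = 0.02128 / 40.087 * s / 1.80655

    ks = math.exp(
        -4276.1 / t + 141.328 - 23.093 * lnt
        + (-13856.0 / t + 324.57 - 47.986 * lnt) * ion_sq
        + (35474.0 / t - 771.54 + 114.723 * lnt) * ion
        - 2698.0 / t * ion ** 1.5
        + 1776.0 / t * ion ** 2
    ) * (1.0 - 0.001005 * s)
    kf = math.exp(1590.2 / t - 12.641 + 1.525 * ion_sq) * (1.0 - 0.001005 * s)

    sws2tot0 = (1.0 + ts / ks) / (1.0 + ts / ks + tf / kf)

    k1 = 10.0 ** -(3633.86 / t - 61.2172 + 9.6777 * lnt - 0.011555 * s + 0.0001152 * s * s)
    k2 = 10.0 ** -(471.78 / t + 25.929 - 3.16967 * lnt - 0.01781 * s + 0.0001122 * s * s)
    k1 /= sws2tot0  # Lueker constants are total scale; work on SWS for pressure
    k2 /= sws2tot0

    kb = math.exp(
        (-8966.9 - 2890.53 * s_sq - 77.942 * s + 1.728 * s ** 1.5 - 0.0996 * s * s) / t
        + 148.0248 + 137.1942 * s_sq + 1.62142 * s
        + (-24.4344 - 25.085 * s_sq - 0.2474 * s) * lnt
        + 0.053105 * s_sq * t
    ) / sws2tot0

    kw = math.exp(
        148.9802 - 13847.26 / t - 23.6521 * lnt
        + (118.67 / t - 5.977 + 1.0495 * lnt) * s_sq
        - 0.01615 * s
    )

    kp1 = math.exp(
        -4576.752 / t + 115.525 - 18.453 * lnt
        + (-106.736 / t + 0.69171) * s_sq + (-0.65643 / t - 0.01844) * s
    )
    kp2 = math.exp(
        -8814.715 / t + 172.0883 - 27.927 * lnt
        + (-160.34 / t + 1.3566) * s_sq + (0.37335 / t - 0.05778) * s
    )
    kp3 = math.exp(
        -3070.75 / t - 18.141
        + (17.27039 / t + 2.81197) * s_sq + (-44.99486 / t - 0.09984) * s
    )
    ksi = math.exp(
        -8904.2 / t + 117.385 - 19.334 * lnt
        + (-458.79 / t + 3.5913) * ion_sq
        + (188.74 / t - 1.5998) * ion
        + (-12.1652 / t + 0.07871) * ion * ion
    ) * (1.0 - 0.001005 * s)

    t100 = t / 100.0
    k0 = math.exp(
        -60.2409 + 93.4517 / t100 + 23.3585 * math.log(t100)
        + s * (0.023517 - 0.023656 * t100 + 0.0047036 * t100 * t100)
    )

    kspa = 10.0 ** (
        -171.945 - 0.077993 * t + 2903.293 / t + 71.595 * math.log10(t)
        + (-0.068393 + 0.0017276 * t + 88.135 / t) * s_sq
        - 0.10018 * s + 0.0059415 * s ** 1.5
    )

    if pb > 0:
        def pc(k, dv, dk):
            return k * math.exp((-dv + 0.5 * dk * pb) * pb / (R * t))

        k1 = pc(k1, -25.5 + 0.1271 * tc, (-3.08 + 0.0877 * tc) * 1e-3)
        k2 = pc(k2, -15.82 - 0.0219 * tc, (1.13 - 0.1475 * tc) * 1e-3)
        kb = pc(kb, -29.48 + 0.1622 * tc - 0.002608 * tc * tc, -2.84e-3)
        kw = pc(kw, -20.02 + 0.1119 * tc - 0.001409 * tc * tc, (-5.13 + 0.0794 * tc) * 1e-3)
        ks = pc(ks, -18.03 + 0.0466 * tc + 0.000316 * tc * tc, (-4.53 + 0.09 * tc) * 1e-3)
        kf = pc(kf, -9.78 - 0.009 * tc - 0.000942 * tc * tc, (-3.91 + 0.054 * tc) * 1e-3)
        kp1 = pc(kp1, -14.51 + 0.1211 * tc - 0.000321 * tc * tc, (-2.67 + 0.0427 * tc) * 1e-3)
        kp2 = pc(kp2, -23.12 + 0.1758 * tc - 0.002647 * tc * tc, (-5.15 + 0.09 * tc) * 1e-3)
        kp3 = pc(kp3, -26.57 + 0.202 * tc - 0.003042 * tc * tc, (-4.08 + 0.0714 * tc) * 1e-3)
        ksi = pc(ksi, -29.48 + 0.1622 * tc - 0.002608 * tc * tc, -2.84e-3)
        kspa = pc(kspa, -48.76 + 0.5304 * tc + 2.8, (-11.76 + 0.3692 * tc) * 1e-3)

    f2t = 1.0 + ts / ks
    s2t = f2t / (1.0 + ts / ks + tf / kf)
    return dict(
        k0=k0, k1=k1 * s2t, k2=k2 * s2t, kb=kb * s2t, kw=kw * s2t,
        kp1=kp1 * s2t, kp2=kp2 * s2t, kp3=kp3 * s2t, ksi=ksi * s2t,
        ks=ks, kf=kf, kspa=kspa, tb=tb, ts=ts, tf=tf, ca=ca, f2t=f2t,
    )


def ta_of_ph(ph, dic, tp, tsi, c):
    h = 10.0 ** -ph
    hfree = h / c["f2t"]
    dd = h * h + c["k1"] * h + c["k1"] * c["k2"]
    alk = dic * c["k1"] * (h + 2.0 * c["k2"]) / dd
    alk += c["tb"] / (1.0 + h / c["kb"])
    alk += c["kw"] / h
    dp = h ** 3 + c["kp1"] * h * h + c["kp1"] * c["kp2"] * h + c["kp1"] * c["kp2"] * c["kp3"]
    alk += tp * (c["kp1"] * c["kp2"] * h + 2 * c["kp1"] * c["kp2"] * c["kp3"] - h ** 3) / dp
    alk += tsi / (1.0 + h / c["ksi"])
    alk -= hfree + c["ts"] / (1.0 + c["ks"] / hfree) + c["tf"] / (1.0 + c["kf"] / hfree)
    return alk


def solve(tc, s, p_dbar, dic_umol, ta_umol, po4_umol, sio3_umol):
    c = constants(tc, s, p_dbar)
    dic, ta = dic_umol * 1e-6, ta_umol * 1e-6
    tp, tsi = po4_umol * 1e-6, sio3_umol * 1e-6
    lo, hi = 2.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ta_of_ph(mid, dic, tp, tsi, c) < ta:
            lo = mid
        else:
            hi = mid
    ph = 0.5 * (lo + hi)
    h = 10.0 ** -ph
    dd = h * h + c["k1"] * h + c["k1"] * c["k2"]
    co3 = dic * c["k1"] * c["k2"] / dd
    co2star = dic * h * h / dd
    return dict(
        pH_total=ph,
        CO3_umolkg=co3 * 1e6,
        omega_ar=co3 * c["ca"] / c["kspa"],
        pCO2_uatm=co2star / c["k0"] * 1e6,
    )


def main():
    out = os.path.join(os.path.dirname(__file__), "..", "tests", "data", "carbonate_reference.csv")
    os.makedirs(os.path.dirname(out), exist_ok=True)
    rows = []
    # 5x5x5 (T, S, DIC) lattice at the surface, TA/PO4/SiO3 fixed
    for t in (2.0, 8.0, 14.0, 20.0, 25.0):
        for s in (30.0, 32.0, 33.5, 35.0, 36.0):
            for dic in (1900.0, 1975.0, 2050.0, 2125.0, 2200.0):
                r = solve(t, s, 0.0, dic, 2300.0, 1.0, 20.0)
                rows.append(("lattice", t, s, 0.0, dic, 2300.0, 1.0, 20.0, r))
    # pressure block for the in-situ correction check
    for p in (0.0, 100.0, 300.0, 600.0, 1000.0, 2000.0):
        r = solve(5.0, 34.0, p, 2250.0, 2350.0, 2.0, 60.0)
        rows.append(("pressure", 5.0, 34.0, p, 2250.0, 2350.0, 2.0, 60.0, r))
    # the standard surface check case
    r = solve(25.0, 35.0, 0.0, 2000.0, 2300.0, 0.0, 0.0)
    rows.append(("spotcheck", 25.0, 35.0, 0.0, 2000.0, 2300.0, 0.0, 0.0, r))

    with open(out, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["block", "T_c", "S", "P_dbar", "DIC_umolkg", "TA_umolkg", "PO4_umolkg",
             "SiO3_umolkg", "pH_total", "CO3_umolkg", "omega_ar", "pCO2_uatm"]
        )
        for block, t, s, p, dic, ta, po4, sio3, r in rows:
            w.writerow(
                [block, t, s, p, dic, ta, po4, sio3,
                 f"{r['pH_total']:.6f}", f"{r['CO3_umolkg']:.4f}",
                 f"{r['omega_ar']:.5f}", f"{r['pCO2_uatm']:.3f}"]
            )
    print(f"wrote {len(rows)} rows to {out}")


if __name__ == "__main__":
    main()
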