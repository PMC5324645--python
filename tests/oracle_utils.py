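"""Independent brute-force oracles kept free of the package's search code."""

#: Published monoisotopic masses (NIST/CODATA), independent of the package's
#: internal table (they agree at the 1e-9 Da level).
NIST_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}


def naive_candidates(target_mass, tol_ppm, ranges, rules):
    """Naive full nested-loop formula search with the same filters and sort.

    Enumerates every (c, h, n, o, s, p) tuple in the ranges — no pruning,
    no analytic hydrogen solving — and applies the plausibility rules
    independently of the package implementation.
    """
    from ivk.chem import ELEMENT_MASSES, MolecularFormula

    m_lo = target_mass * (1 - tol_ppm * 1e-6)
    m_hi = target_mass * (1 + tol_ppm * 1e-6)
    hits = []
    for c in range(ranges.c[0], ranges.c[1] + 1):
        for h in range(ranges.h[0], ranges.h[1] + 1):
            for n in range(ranges.n[0], ranges.n[1] + 1):
                for o in range(ranges.o[0], ranges.o[1] + 1):
                    for s in range(ranges.s[0], ranges.s[1] + 1):
                        for p in range(ranges.p[0], ranges.p[1] + 1):
                            mass = (c * ELEMENT_MASSES["C"] + h * ELEMENT_MASSES["H"]
                                    + n * ELEMENT_MASSES["N"] + o * ELEMENT_MASSES["O"]
                                    + s * ELEMENT_MASSES["S"] + p * ELEMENT_MASSES["P"])
                            if not (m_lo <= mass <= m_hi):
                                continue
                            if not _rules_ok(c, h, n, o, s, p, rules):
                                continue
                            f = MolecularFormula(c=c, h=h, n=n, o=o, s=s, p=p)
                            err = (target_mass - mass) / mass * 1e6
                            hits.append((f, mass, err))
    hits.sort(key=lambda t: (abs(t[2]), t[0].n + t[0].s + t[0].p, t[0].o,
                             t[0].hill()))
    return hits


def _rules_ok(c, h, n, o, s, p, rules):
    # independent restatement of the plausibility filters
    if rules.valence_cap and h > 2 * c + 2 + n + p:
        return False
    if not (rules.hc_min <= h / c <= rules.hc_max):
        return False
    if o / c > rules.oc_max or n / c > rules.nc_max or s / c > rules.sc_max:
        return False
    d = 1 + c - h / 2 + n / 2 + p / 2
    if rules.require_integer_dbe and d != int(d):
        return False
    if d < rules.dbe_min:
        return False
    if rules.parity_rule and (d != int(d) or d < 0):
        return False
    return True
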