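"""Independent literal re-implementations of the scoring rubrics and metrics.

Written as flat nested conditionals, deliberately duplicating nothing from
``dicscore.scoring`` — these are the oracles the implementation is checked
against on factorial grids straddling every band boundary.  Inputs are the
already-resolved quantities (prolongations/ratios), so the oracles exercise
only the banding logic.
"""


def oracle_ksth(platelets, pt_prol, aptt_prol, d_dimer, fibrinogen):
    total = 0
    if platelets <= 100:
        total += 1
    if pt_prol >= 3:
        total += 1
    if aptt_prol >= 5:
        total += 1
    if d_dimer >= 1.0:
        total += 1
    if fibrinogen <= 1.5:
        total += 1
    return total


def oracle_isth(platelets, pt_prol, d_dimer, fibrinogen):
    total = 0
    if platelets <= 50:
        total += 2
    elif platelets <= 100:
        total += 1
    if pt_prol >= 6:
        total += 2
    elif pt_prol >= 3:
        total += 1
    if d_dimer >= 5.0:
        total += 3
    elif d_dimer >= 1.0:
        total += 2
    if fibrinogen <= 1.0:
        total += 1
    return total


def oracle_jaam(platelets, prior, pt_ratio, fdp, fibrinogen, sirs):
    total = 0
    drop = None
    if prior is not None and prior > 0:
        drop = (prior - platelets) / prior
    if platelets < 80:
        total += 3
    elif drop is not None and drop > 0.50:
        total += 3
    elif 80 <= platelets < 120:
        total += 1
    elif drop is not None and drop > 0.30:
        total += 1
    if pt_ratio >= 1.2:
        total += 1
    if fdp >= 25:
        total += 3
    elif fdp >= 10:
        total += 1
    if fibrinogen <= 3.5:
        total += 1
    if sirs >= 3:
        total += 1
    return total


def oracle_rjaam(platelets, prior, pt_ratio, fdp, fibrinogen, sirs):
    total = oracle_jaam(platelets, prior, pt_ratio, fdp, fibrinogen, sirs)
    if fibrinogen <= 3.5:
        total -= 1
    return total


def oracle_jmhw(platelets, pt_ratio, fdp, fibrinogen,
                underlying_disease, bleeding, organ_failure):
    total = 0
    if platelets <= 50:
        total += 3
    elif platelets <= 80:
        total += 2
    elif platelets <= 120:
        total += 1
    if pt_ratio >= 1.67:
        total += 2
    elif pt_ratio >= 1.25:
        total += 1
    if fdp >= 40:
        total += 3
    elif fdp >= 20:
        total += 2
    elif fdp >= 10:
        total += 1
    if fibrinogen <= 1.0:
        total += 2
    elif fibrinogen <= 1.5:
        total += 1
    if underlying_disease:
        total += 1
    if bleeding:
        total += 1
    if organ_failure:
        total += 1
    return total


def oracle_metrics(labelled):
    """Metrics by direct counting over (dic_positive, expired) pairs.

    Returns dict of fractions (None where the denominator vanishes).
    """
    tp = sum(1 for pos, exp in labelled if pos and exp)
    fp = sum(1 for pos, exp in labelled if pos and not exp)
    fn = sum(1 for pos, exp in labelled if not pos and exp)
    tn = sum(1 for pos, exp in labelled if not pos and not exp)
    n = tp + fp + fn + tn

    def frac(num, den):
        return num / den if den else None

    return {
        "sensitivity": frac(tp, tp + fn),
        "specificity": frac(tn, tn + fp),
        "ppv": frac(tp, tp + fp),
        "npv": frac(tn, tn + fn),
        "accuracy": frac(tp + tn, n),
    }
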