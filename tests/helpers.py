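"""Independent oracles used by the test suite.

These re-evaluate the classification rule and Fisher's exact test with
deliberately naive code (plain Python loops, exact combinatorics) so they
stay independent of the vectorized implementations they check.
"""

from __future__ import annotations

from math import comb


def literal_responder_rule(time, ca, windows, amp_min=50.0, sd_multiple=3.0, smooth=3):
    """Word-for-word re-evaluation of the responder rule on one trace.

    A cell responds if the calcium rise during agonist application exceeds
    ``amp_min`` and the highest derivative value during the application
    exceeds ``sd_multiple`` times the SD of the derivative during baseline.
    Plain-Python moving average and finite differences; uniform sampling
    assumed.
    """
    time = list(map(float, time))
    ca = list(map(float, ca))
    n = len(ca)
    half = smooth // 2
    sm = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        sm.append(sum(ca[lo:hi]) / (hi - lo))
    deriv = []
    for i in range(n):
        if i == 0:
            d = (sm[1] - sm[0]) / (time[1] - time[0])
        elif i == n - 1:
            d = (sm[-1] - sm[-2]) / (time[-1] - time[-2])
        else:
            d = (sm[i + 1] - sm[i - 1]) / (time[i + 1] - time[i - 1])
        deriv.append(d)
    base_w = windows.baseline
    app_w = windows.applications[0]
    base = [i for i, t in enumerate(time) if base_w.t_start <= t <= base_w.t_end]
    app = [i for i, t in enumerate(time) if app_w.t_start <= t <= app_w.t_end]
    baseline = sum(ca[i] for i in base) / len(base)
    amplitude = max(ca[i] for i in app) - baseline
    bd = [deriv[i] for i in base]
    mean_bd = sum(bd) / len(bd)
    sd = (sum((x - mean_bd) ** 2 for x in bd) / len(bd)) ** 0.5
    max_deriv = max(deriv[i] for i in app)
    return amplitude > amp_min and max_deriv > sd_multiple * sd


def fisher_exact_enumeration(k1, n1, k2, n2):
    """Two-sided Fisher exact p by hypergeometric enumeration of one margin.

    Conditions on both margins of the 2x2 table ((k1, n1-k1), (k2, n2-k2))
    and sums P(X = k) over every k whose point probability does not exceed
    that of the observed table (with a relative tolerance for float ties).
    """
    total = n1 + n2
    successes = k1 + k2

    def pmf(k):
        if k < 0 or k > n1 or successes - k < 0 or successes - k > n2:
            return 0.0
        return comb(n1, k) * comb(n2, successes - k) / comb(total, successes)

    p_obs = pmf(k1)
    return sum(p for k in range(successes + 1)
               if (p := pmf(k)) <= p_obs * (1.0 + 1e-9))
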