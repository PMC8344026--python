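"""Independent reference implementations used as test oracles.

Deliberately written with the stdlib ``math`` module, per scalar record,
sharing no code with the package's vectorized implementations.
"""

import math


def gompertz_cdf(t, theta, gamma, lam):
    if abs(gamma) < 1e-8:
        inner = lam * t
    else:
        inner = (lam / gamma) * (math.exp(gamma * t) - 1.0)
    return (1.0 - math.exp(-inner)) ** theta


def gompertz_pdf(t, theta, gamma, lam):
    if abs(gamma) < 1e-8:
        inner = lam * t
    else:
        inner = (lam / gamma) * (math.exp(gamma * t) - 1.0)
    base = 1.0 - math.exp(-inner)
    if base == 0.0:
        return lam if theta == 1.0 else (0.0 if theta > 1.0 else math.inf)
    return theta * lam * math.exp(gamma * t) * math.exp(-inner) * base ** (theta - 1.0)


def gompertz_plateau(theta, gamma, lam):
    if gamma >= 0:
        return 1.0
    return (1.0 - math.exp(lam / gamma)) ** theta


def competing_loglik(records, cause1, cause2):
    """Term-by-term competing-risks log-likelihood.

    ``records``: iterable of (time, event, {name: value}); ``cause1``/
    ``cause2``: dicts with keys theta, gamma, lam, beta ({name: coef}).
    """
    total = 0.0
    for t, event, x in records:
        rates = []
        for cm in (cause1, cause2):
            lp = sum(coef * x[name] for name, coef in cm["beta"].items())
            rates.append(cm["lam"] * math.exp(lp))
        if event == 1:
            total += math.log(gompertz_pdf(t, cause1["theta"], cause1["gamma"], rates[0]))
        elif event == 2:
            total += math.log(gompertz_pdf(t, cause2["theta"], cause2["gamma"], rates[1]))
        else:
            s = (1.0
                 - gompertz_cdf(t, cause1["theta"], cause1["gamma"], rates[0])
                 - gompertz_cdf(t, cause2["theta"], cause2["gamma"], rates[1]))
            total += math.log(s)
    return total
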