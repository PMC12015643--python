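"""Small shared pieces for the adaptive Metropolis-within-Gibbs samplers.

Both fitting surfaces (the hierarchical distance-sampling model and the
mixed-effects models) use blocked random-walk Metropolis updates whose
proposal scales adapt during warmup toward a target acceptance rate, with
conjugate Gibbs draws wherever the conditional is available in closed form.
"""

from __future__ import annotations

import numpy as np

TARGET_ACCEPT = 0.35


def adapt_log_scale(log_scale, accept_rate, iteration, target=TARGET_ACCEPT):
    """Robbins-Monro style scale adaptation (warmup only)."""
    step = min(0.5, 2.0 / np.sqrt(iteration + 10.0))
    return log_scale + step * (accept_rate - target)


def half_normal_logpdf(x, scale):
    """log density of |N(0, scale^2)| at x >= 0 (unnormalized constant kept)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x >= 0,
        -0.5 * (x / scale) ** 2 + np.log(2.0) - np.log(scale) - 0.5 * np.log(2 * np.pi),
        -np.inf,
    )
    return out


def normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)


def rhat_ess(chain_draws: np.ndarray):
    """Split-R-hat and bulk ESS for draws shaped (chain, draw) via arviz."""
    import arviz as az

    data = az.convert_to_dataset({"x": np.asarray(chain_draws)})
    r = float(np.asarray(az.rhat(data)["x"]).reshape(()))
    e = float(np.asarray(az.ess(data)["x"]).reshape(()))
    return r, e
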