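"""MCMC convergence diagnostics: split-R̂ and effective sample size."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientChainsError
from .sampler import PosteriorDraws


def check_convergence(
    draws: PosteriorDraws,
    rhat_max: float = 1.1,
    ess_min: float = 100.0,
) -> dict:
    """Split-R̂ and bulk ESS for every scalar parameter.

    Passes iff every R̂ ≤ ``rhat_max`` and every ESS ≥ ``ess_min``.
    Returns ``{"passed", "max_rhat", "min_ess", "table"}`` where ``table``
    is a DataFrame indexed by flattened parameter name.

    Raises :class:`InsufficientChainsError` with a single chain — split-R̂
    needs at least two.
    """
    import arviz as az

    if draws.n_chains < 2:
        raise InsufficientChainsError(
            "convergence diagnostics require at least 2 chains"
        )
    idata = draws.to_inference_data()
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = []
    for name in idata.posterior.data_vars:
        r = np.atleast_1d(rhat[name].values).ravel()
        e = np.atleast_1d(ess[name].values).ravel()
        if r.size == 1:
            rows.append((name, float(r[0]), float(e[0])))
        else:
            for i, (ri, ei) in enumerate(zip(r, e)):
                rows.append((f"{name}[{i}]", float(ri), float(ei)))
    table = pd.DataFrame(rows, columns=["parameter", "rhat", "ess"])
    table = table.set_index("parameter")
    finite = table["rhat"].replace([np.inf, -np.inf], np.nan).dropna()
    max_rhat = float(finite.max()) if len(finite) else 1.0
    min_ess = float(table["ess"].min()) if len(table) else np.inf
    return {
        "passed": bool(max_rhat <= rhat_max and min_ess >= ess_min),
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "rhat_max": rhat_max,
        "ess_min": ess_min,
        "table": table,
    }
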