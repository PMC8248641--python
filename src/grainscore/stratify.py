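"""Whole-grain exposure groups via age-stratum-specific tertiles.

Participants reporting no whole-grain food are the ``no_wg`` group; the
remaining consumers are split at the unweighted empirical 1/3 and 2/3
quantiles of WG grams within their age stratum (child 1-18 y, adult >= 19 y)
into ``low_wg`` / ``mid_wg`` / ``high_wg``.  The quantile is the inverse-CDF
(type-1) definition and boundary-valued participants fall to the lower
group, so assignment is deterministic and order-independent.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from . import schema
from .errors import StratificationError

logger = logging.getLogger(__name__)


def _type1_quantile(sorted_values: np.ndarray, p: float) -> float:
    n = sorted_values.size
    idx = max(int(math.ceil(n * p)) - 1, 0)
    return float(sorted_values[idx])


def assign_wg_groups(exposures: pd.DataFrame, ages: pd.Series) -> pd.DataFrame:
    """Assign each participant a WG intake group.

    Parameters
    ----------
    exposures : DataFrame indexed by participant_id with a ``wg_grams``
        column (as produced by :func:`grainscore.classify.compute_wg_exposure`).
    ages : Series of age in years aligned on participant_id.

    Returns a DataFrame indexed by participant_id with ``stratum``, ``group``
    (ordered categorical no_wg < low_wg < mid_wg < high_wg) and the ordinal
    ``group_score`` 0-3.
    """
    ages = ages.reindex(exposures.index)
    if ages.isna().any():
        missing = list(exposures.index[ages.isna()])[:5]
        raise StratificationError(f"participants without an age: {missing}")
    if (ages < 1).any():
        raise StratificationError("ages must be >= 1 year")

    wg = exposures["wg_grams"].to_numpy(dtype=float)
    stratum = np.where(ages.to_numpy(dtype=float) >= schema.ADULT_AGE_MIN, "adult", "child")
    group = np.full(len(exposures), "no_wg", dtype=object)

    for s in schema.STRATA:
        in_stratum = stratum == s
        if not in_stratum.any():
            continue
        mask = in_stratum & (wg > 0)
        consumers = wg[mask]
        if consumers.size < 3:
            raise StratificationError(
                f"stratum {s!r} has only {consumers.size} WG consumers; "
                "at least 3 are needed to form tertiles"
            )
        srt = np.sort(consumers)
        q1 = _type1_quantile(srt, 1.0 / 3.0)
        q2 = _type1_quantile(srt, 2.0 / 3.0)
        if q1 == q2:
            logger.warning(
                "stratum %s: tied tertile boundaries (q1 = q2 = %g); "
                "boundary-valued consumers all fall to the lower group", s, q1,
            )
        g = np.where(consumers <= q1, "low_wg", np.where(consumers <= q2, "mid_wg", "high_wg"))
        group[mask] = g

    out = pd.DataFrame(index=exposures.index.copy())
    out["stratum"] = stratum
    out["group"] = pd.Categorical(group, categories=list(schema.WG_GROUPS), ordered=True)
    out["group_score"] = out["group"].cat.codes.astype(int)
    return out
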