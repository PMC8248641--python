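"""Modified Nutrient Rich Food Index 9.3 for the total diet.

The index scores a whole day's intake: each nutrient amount is first
standardised to the energy basis (default 2000 kcal), expressed as a percent
of its daily value (DV), then the nine encourage-nutrient contributions are
capped (default 100%) and summed while the three limit-nutrient
contributions are summed uncapped and subtracted:

    score = sum_i min(cap, 100 * per_basis(amount_i) / DV_i)
          - sum_j 100 * per_basis(amount_j) / DV_j

Energy-adjust first, then %DV, then cap — the only order under which the
per-2000-kcal phrasing and the cap are both well defined per participant.
With nine encourage nutrients and a 100% cap the theoretical maximum is 900
(all encourage DVs met, zero limit intake).  Scores are undefined for
zero-energy intakes (NaN, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog_io import DVTable
from .errors import ConfigurationError, ScoringError

logger = logging.getLogger(__name__)


def per_basis(amount: float | np.ndarray, energy_kcal: float | np.ndarray,
              basis_kcal: float = 2000.0) -> float | np.ndarray:
    """Standardise a daily amount to ``basis_kcal`` of energy
    (``amount * basis / energy``).  Scalar zero energy raises; array input
    returns NaN for zero-energy rows."""
    if np.isscalar(energy_kcal) or np.ndim(energy_kcal) == 0:
        if energy_kcal <= 0:
            raise ScoringError("energy must be positive to energy-standardise an amount")
        return amount * basis_kcal / energy_kcal
    energy = np.asarray(energy_kcal, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(amount, dtype=float) * basis_kcal / energy
    return np.where(energy > 0, out, np.nan)


@dataclass
class NRFResult:
    participant_id: str
    encourage_subscore: float
    limit_subscore: float
    score: float
    per_nutrient: dict[str, float]


def nrf93_profiles(profiles: pd.DataFrame, dv: DVTable) -> pd.DataFrame:
    """Score every intake profile.

    ``profiles`` is the frame from
    :func:`grainscore.classify.build_intake_profiles` (needs ``energy_kcal``
    and the DV nutrients).  Returns a frame indexed like ``profiles`` with
    ``encourage_subscore``, ``limit_subscore``, ``score`` and one
    ``pct_<nutrient>`` column per DV nutrient (capped for encourage
    nutrients, uncapped for limit nutrients).  Zero-energy rows score NaN.
    """
    missing = [n for n in dv.nutrients if n not in profiles.columns]
    if missing:
        raise ConfigurationError(f"profiles lack DV nutrients: {missing}")

    energy = profiles["energy_kcal"].to_numpy(dtype=float)
    n_zero = int((energy <= 0).sum())
    if n_zero:
        logger.warning("NRF 9.3 undefined for %d zero-energy participants; scored NaN", n_zero)

    out = pd.DataFrame(index=profiles.index.copy())
    enc_total = np.zeros(len(profiles))
    lim_total = np.zeros(len(profiles))
    for nid, dval in dv.encourage.items():
        pct = 100.0 * per_basis(profiles[nid].to_numpy(dtype=float), energy,
                                dv.energy_basis_kcal) / dval
        pct = np.minimum(pct, dv.cap_percent)
        out[f"pct_{nid}"] = pct
        enc_total = enc_total + pct
    for nid, dval in dv.limit.items():
        pct = 100.0 * per_basis(profiles[nid].to_numpy(dtype=float), energy,
                                dv.energy_basis_kcal) / dval
        out[f"pct_{nid}"] = pct
        lim_total = lim_total + pct

    out.insert(0, "score", enc_total - lim_total)
    out.insert(0, "limit_subscore", lim_total)
    out.insert(0, "encourage_subscore", enc_total)
    return out


def nrf93(profile: pd.Series, dv: DVTable) -> NRFResult:
    """Score a single intake profile (raises ScoringError on zero energy)."""
    if profile["energy_kcal"] <= 0:
        raise ScoringError("NRF 9.3 undefined for zero-energy intake")
    frame = profiles_from_series(profile)
    res = nrf93_profiles(frame, dv).iloc[0]
    return NRFResult(
        participant_id=str(frame.index[0]),
        encourage_subscore=float(res["encourage_subscore"]),
        limit_subscore=float(res["limit_subscore"]),
        score=float(res["score"]),
        per_nutrient={n: float(res[f"pct_{n}"]) for n in dv.nutrients},
    )


def profiles_from_series(profile: pd.Series) -> pd.DataFrame:
    frame = profile.to_frame().T
    frame.index.name = "participant_id"
    return frame.astype(float)
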