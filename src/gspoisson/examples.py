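"""Packaged example design problems.

``moderate_osah_trial`` is a hypothetical two-arm obstructive sleep
apnea-hypopnea (OSAH) trial with the apnea-hypopnea index (AHI, events per
hour of sleep) as the count endpoint.  The control-arm mean AHI may fall
anywhere in the moderate-disease range [15, 30], so both the null and the
powered alternative are composite over that interval; the trial is powered
for an AHI reduction of 2.25 events per hour (a 15% reduction at the lower
end of the range), with one-sided alpha 0.05 and power 0.8.  Expected sample
sizes are reported at a control rate of 15.
"""

from __future__ import annotations

from .types import DesignProblem

__all__ = ["moderate_osah_trial"]


def moderate_osah_trial() -> DesignProblem:
    """The moderate-OSAH design problem used throughout the documentation."""
    return DesignProblem(
        lambda_null=(15.0, 30.0),
        lambda_alt=(15.0, 30.0),
        delta=2.25,
        alpha=0.05,
        beta=0.2,
        lambda_ess=15.0,
    )
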