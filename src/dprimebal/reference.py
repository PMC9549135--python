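"""Published group-level reference data bundled for worked examples.

These are summary values from a study of thirteen trained male swimmers
who performed 200-800 m maximal time trials and two exhaustive 50 m
interval sessions (work/relief 2:1 and 4:1, passive rest): the group-mean
race times, the group-mean model parameters, and the per-swimmer session
time constants solved at observed exhaustion.  Individual raw trial and
lap data were not published; these tables are the inputs the agreement
statistics can be recomputed from.
"""

from __future__ import annotations

import pandas as pd

from .agreement import PairedSample
from .cs_model import TimeTrial

#: group-mean maximal performances: distance (m) -> mean time (s)
GROUP_MEAN_TRIALS = [
    TimeTrial(200.0, 136.0),
    TimeTrial(400.0, 297.0),
    TimeTrial(600.0, 461.0),
    TimeTrial(800.0, 624.0),
]

#: group-mean model parameters (mean of the individual fits)
GROUP_CS_MEAN = 1.23  # m/s
GROUP_CS_SD = 0.09
GROUP_D_PRIME_MEAN = 33.69  # m
GROUP_D_PRIME_SD = 8.65

#: per-swimmer tau (s) solved iteratively at observed exhaustion in the
#: 2:1 and 4:1 work/relief sessions; subject 11's 4:1 value is an extreme
#: outlier of unclear origin and is the usual exclusion-reanalysis case
TAU_TABLE = pd.DataFrame(
    {
        "subject": [str(i) for i in range(1, 14)],
        "tau_2to1_s": [86.0, 75.5, 73.5, 81.0, 68.4, 70.0, 46.0,
                       71.5, 65.0, 169.0, 78.5, 77.7, 69.5],
        "tau_4to1_s": [86.0, 205.0, 58.0, 49.5, 45.0, 100.0, 24.5,
                       51.0, 250.0, 500.0, 4000.0, 57.0, 36.5],
    }
)

OUTLIER_SUBJECT = "11"


def tau_paired_sample() -> PairedSample:
    """The two session tau vectors as a paired sample (2:1 minus 4:1)."""
    return PairedSample(
        ids=tuple(TAU_TABLE.subject),
        a=tuple(TAU_TABLE.tau_2to1_s),
        b=tuple(TAU_TABLE.tau_4to1_s),
        units="s",
    )
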