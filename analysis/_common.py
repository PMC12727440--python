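"""Shared configuration for the numbered analysis scripts.

Every script recomputes its stage deterministically from this configuration
(the pipeline is seconds at this scale), so no binary intermediates need to
be kept between steps; only text tables land in results/.
"""

from pathlib import Path

from lesionbench.config import default_study_config

RESULTS = Path(__file__).resolve().parent.parent / "results"

#: 6 lesion profiles x 4 matched controls = 24 simulated sets, 64^3 @ 1 mm
STUDY_SEED = 42


def study_config():
    return default_study_config(n_profiles=6, n_hc_per_tbi=4, seed=STUDY_SEED)
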