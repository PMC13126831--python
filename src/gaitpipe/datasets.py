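"""Small bundled datasets from a published pediatric markerless-gait
validation study (12 participants recorded simultaneously with a
marker-based optoelectronic system and a single sagittal video camera).

These ship as plain CSV inside the package and serve as worked examples and
regression anchors for the agreement statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_DATA = resources.files(__package__) / "data"


def load_cycle_time_validation() -> pd.DataFrame:
    """Per-participant mean gait cycle times (seconds) from the validation
    subgroup: 6 children with juvenile idiopathic arthritis (JIA) and 6
    typically developing (TD) peers, measured by the marker-based reference
    (``reference_s``) and the markerless method (``proposed_s``)."""
    with resources.as_file(_DATA / "validation_cycle_times.csv") as path:
        return pd.read_csv(path)


def load_reference_kinematics() -> pd.DataFrame:
    """Published cohort-level sagittal kinematic parameters (Min/Max/ROM in
    degrees) for hip, knee and ankle, by group: the full JIA cohort, the
    subgroup with active lower-limb arthritis, and TD controls."""
    with resources.as_file(_DATA / "reference_kinematic_parameters.csv") as path:
        return pd.read_csv(path)
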