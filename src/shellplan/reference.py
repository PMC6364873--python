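"""Reference clinical shell-constraint data.

Per-patient maximum shell doses (cGy) at 1, 3 and 5 cm from the target,
as obtained by prioritized pre-optimization for a published clinical
cohort of 20 vestibular-schwannoma radiosurgery patients.  These are the
values whose population means define the fixed (non-individualized) shell
constraints in the fixed-constraint experiment, and the only external
numbers this package consumes.
"""

from __future__ import annotations

import numpy as np

SHELL_DISTANCES_CM = (1.0, 3.0, 5.0)

#: rows = patients 1..20, columns = shells at 1, 3, 5 cm; units cGy
CLINICAL_SHELL_DMAX_CGY = np.array([
    [427, 156, 112],
    [374, 140, 106],
    [430, 157, 117],
    [423, 173, 138],
    [458, 171, 133],
    [426, 155, 120],
    [428, 168, 129],
    [370, 146, 98],
    [390, 123, 88],
    [344, 108, 74],
    [423, 170, 105],
    [417, 174, 137],
    [368, 135, 107],
    [475, 181, 124],
    [357, 119, 84],
    [536, 210, 162],
    [396, 165, 123],
    [471, 198, 167],
    [522, 181, 134],
    [486, 200, 149],
], dtype=float)


def clinical_shell_constraint_sets():
    """The reference table as per-patient ShellConstraintSet objects."""
    from .mco import ShellConstraintSet
    out = []
    for row in CLINICAL_SHELL_DMAX_CGY:
        out.append(ShellConstraintSet(
            distances_cm=SHELL_DISTANCES_CM,
            dmax_cgy=dict(zip(SHELL_DISTANCES_CM, row))))
    return out
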