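"""Shared constructed inputs for the diagnostic tests."""

import numpy as np

from migranet.inconsistency import DesignContrasts, DesignLevel
from migranet.trial_data import treatment


def single_contrast_design(pair, y, w, studies=("S",), q_het=0.0):
    a, b = sorted(treatment(x) for x in pair)
    return DesignLevel(
        treatments=frozenset((a, b)),
        baseline=a,
        contrasts=[(a, b)],
        y=np.array([float(y)]),
        W=np.array([[float(w)]]),
        studies=list(studies),
        q_het=q_het,
    )


def noise_free_triangle() -> DesignContrasts:
    """Exactly additive contrasts: y_AB=0.5, y_BC=0.7, y_AC=1.2."""
    return DesignContrasts(
        endpoint=None,
        treatments=[treatment(t) for t in "ABC"],
        designs=[
            single_contrast_design("AB", 0.5, 1.0),
            single_contrast_design("BC", 0.7, 1.0),
            single_contrast_design("AC", 1.2, 1.0),
        ],
    )
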