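import numpy as np


def truth_theta(truth, mode="constrained"):
    """Full joint parameter vector at the ground truth, region order as generated."""
    regions = ("cerebellum", "parietal", "hippocampus", "striatum")
    kin = np.concatenate([truth.kinetics[r].as_array() for r in regions])
    if mode == "constrained":
        aif = np.concatenate([truth.hill.as_array(), truth.ratio.as_array()])
    else:
        aif = truth.feng.as_array()
    return np.concatenate([aif, kin])
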