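"""Fusing the three per-view score volumes into one 3D label volume.

``score_sum`` (default) sums per-class scores over the views and takes the
voxelwise argmax; ``label_vote`` first takes each view's argmax labels and
then a per-voxel majority vote, breaking vote ties by the summed scores and
remaining ties toward the lowest class index.  Both modes are symmetric in
the view order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ViewProbabilities
from .volume import LabelVolume

MODES = ("score_sum", "label_vote")


@dataclass
class FusedVolume:
    labels: LabelVolume
    per_class_support: np.ndarray  # (n_classes, nx, ny, nz)


def fuse_views(pa: ViewProbabilities, ps: ViewProbabilities, pc: ViewProbabilities,
               mode: str = "score_sum",
               spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> FusedVolume:
    if mode not in MODES:
        raise ValueError(f"unknown fusion mode {mode!r}")
    shapes = {pa.scores.shape, ps.scores.shape, pc.scores.shape}
    if len(shapes) != 1:
        raise ValueError(f"score volumes disagree in shape: {sorted(shapes)}")
    support = pa.scores.astype(np.float64) + ps.scores + pc.scores
    if mode == "score_sum":
        labels = np.argmax(support, axis=0)  # argmax takes the lowest index on ties
    else:
        k = support.shape[0]
        votes = np.zeros_like(support)
        for p in (pa, ps, pc):
            lab = np.argmax(p.scores, axis=0)
            votes += (lab[None] == np.arange(k)[:, None, None, None])
        # majority vote; ties broken by summed scores, then lowest label.
        # lexicographic key: votes first, support second (support < 3 bounds it)
        key = votes * 4.0 + support / (support.max() + 1.0)
        labels = np.argmax(key, axis=0)
    return FusedVolume(
        labels=LabelVolume(labels.astype(np.uint8), spacing=spacing),
        per_class_support=support.astype(np.float32),
    )
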