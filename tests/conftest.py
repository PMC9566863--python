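import numpy as np
import pytest

from flyquant import foxo, synth


@pytest.fixture(scope="session")
def default_scene():
    """One medium nuclei scene shared by read-only tests."""
    spec = synth.NucleiSceneSpec(seed=3, n_nuclei=8)
    lamin, foxo_stack, truth = synth.generate_nuclei_stack(spec)
    return spec, lamin, foxo_stack, truth


@pytest.fixture(scope="session")
def segmented_scene(default_scene):
    """The default scene run through 2D segmentation + 3D reconstruction."""
    spec, lamin, foxo_stack, truth = default_scene
    cfg = foxo.SegmentationConfig()
    labels, centroids, t = foxo.segment_nuclei_2d(lamin, cfg)
    masks = foxo.reconstruct_nuclei_3d(lamin, labels, cfg, threshold=t)
    return spec, lamin, foxo_stack, truth, labels, masks


def footprint_iou_matches(truth_labels: np.ndarray, masks, min_iou: float = 0.5):
    """Greedy truth-to-recovered footprint matching at an IoU floor.

    Returns (n_matched, n_spurious): spurious = recovered nuclei that
    match no true nucleus at the floor.
    """
    truth_2d = truth_labels.max(axis=0)
    n_true = int(truth_labels.max())
    matched_masks = set()
    n_matched = 0
    for k in range(1, n_true + 1):
        tf = truth_2d == k
        best, best_i = 0.0, None
        for i, m in enumerate(masks):
            if i in matched_masks:
                continue
            inter = int((m.footprint & tf).sum())
            if inter == 0:
                continue
            iou = inter / int((m.footprint | tf).sum())
            if iou > best:
                best, best_i = iou, i
        if best >= min_iou and best_i is not None:
            matched_masks.add(best_i)
            n_matched += 1
    n_spurious = len(masks) - len(matched_masks)
    return n_matched, n_spurious
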