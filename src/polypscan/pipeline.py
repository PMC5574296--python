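"""High-level experiment drivers tying the stages together.

These functions reproduce, at desk scale on synthetic fixtures, the study
design of the pipeline: train the CNN on labelled windows, freeze it as a
feature extractor, fuse its fc2 activations with color-wavelet texture
features, train a linear SVM on the fused vectors, and evaluate on a
held-out stratified split — plus the ablation comparing the fused model
with each single feature family.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .cnn import CnnFeatureExtractor
from .detect import PolypDetector
from .fusion import FusedPolypClassifier, evaluate, fuse
from .synthetic import FixtureSpec, LabelledWindowSet, make_dataset
from .wavelet import ColorWaveletExtractor

__all__ = ["train_detector", "fusion_benchmark", "localization_benchmark"]


def train_detector(
    windows,
    labels,
    cnn_epochs: int = 10,
    lr: float = 1e-3,
    momentum: float = 0.9,
    batch_size: int = 16,
    C: float = 1.0,
    seed: int = 0,
    **detector_kwargs,
) -> PolypDetector:
    """Train the full two-branch pipeline on labelled windows."""
    cw = ColorWaveletExtractor()
    cnn = CnnFeatureExtractor(epochs=cnn_epochs, lr=lr, momentum=momentum, batch_size=batch_size, random_state=seed)
    cnn.fit(windows, labels)
    fused = fuse(cw.transform(windows), cnn.transform(windows))
    clf = FusedPolypClassifier(C=C, random_state=seed).fit(fused, labels)
    return PolypDetector(cw_extractor=cw, cnn_extractor=cnn, classifier=clf, positive_class=1, **detector_kwargs)


def fusion_benchmark(
    n_polyp: int = 100,
    n_nonpolyp: int = 200,
    seed: int = 0,
    cnn_epochs: int = 3,
    test_size: float = 0.3,
    spec: FixtureSpec | None = None,
    dataset: LabelledWindowSet | None = None,
) -> dict:
    """Held-out comparison of fused vs single-family models at one seed.

    Generates a seeded window set (1:2 polyp:nonpolyp by default), splits it
    stratified 70/30, trains the CNN on the training windows only, then
    trains three SVMs on identical splits: color-wavelet features alone,
    CNN features alone, and the fused vectors.  Returns the held-out
    metrics of all three and the fitted components.
    """
    if dataset is None:
        dataset = make_dataset(n_polyp, n_nonpolyp, spec=spec, seed=seed)
    X = dataset.pixel_array()
    y = dataset.labels
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), test_size=test_size, stratify=y, random_state=seed
    )
    cw = ColorWaveletExtractor()
    cnn = CnnFeatureExtractor(epochs=cnn_epochs, random_state=seed)
    cnn.fit(X[idx_train], y[idx_train])

    cw_all = cw.transform(X)
    cnn_all = cnn.transform(X)
    fused_all = fuse(cw_all, cnn_all)

    results = {}
    models = {}
    for name, feats, validate in (("cw", cw_all, False), ("cnn", cnn_all, False), ("fused", fused_all, True)):
        clf = FusedPolypClassifier(random_state=seed, validate_length=validate)
        clf.fit(feats[idx_train], y[idx_train])
        pred = clf.predict(feats[idx_test])
        results[name] = evaluate(pred, y[idx_test], positive_class=1)
        models[name] = clf
    return {
        "metrics": results,
        "dataset": dataset,
        "split": (idx_train, idx_test),
        "extractors": {"cw": cw, "cnn": cnn},
        "models": models,
    }


def localization_benchmark(detector: PolypDetector, n_frames: int = 10, seed: int = 0, tmp_path=None, spec: FixtureSpec | None = None) -> dict:
    """Marker-inside-ellipse hit rate on a synthetic drifting-polyp video."""
    import tempfile
    from pathlib import Path

    from .frames import read_frames
    from .synthetic import make_video

    if tmp_path is None:
        tmp_dir = tempfile.mkdtemp(prefix="polypscan_")
        video_path = Path(tmp_dir) / "synthetic.avi"
    else:
        video_path = Path(tmp_path) / "synthetic.avi"
    track = make_video(n_frames, video_path, spec=spec, seed=seed)
    frames = read_frames(video_path, kind="video")
    hits, per_frame = 0, []
    for frame, ellipse in zip(frames, track):
        markers = detector.detect_frame(frame)
        hit = False
        if markers:
            best = max(markers, key=lambda m: m.mean_score)
            hit = ellipse.contains(*best.center)
        hits += hit
        per_frame.append({"frame": frame.index, "hit": bool(hit), "n_markers": len(markers)})
    return {"hits": hits, "n_frames": n_frames, "per_frame": per_frame, "video": str(video_path), "track": track}
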