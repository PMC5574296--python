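"""From per-window SVM decisions to per-frame polyp markers.

Positive windows of one frame are grouped by single linkage on their
centers (a polyp typically fires several overlapping windows); within a
group, windows scoring at least ``score_fraction`` of the group's maximum
are kept and their centers averaged into one marker.  Markers are drawn as
circles on the frame and the annotated sequence can be written back to a
lossless AVI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import avi
from .exceptions import BoundsError, EmptyInputError
from .frames import DEFAULT_STRIDE, WINDOW_SIZE, Frame, Window, generate_windows


@dataclass(frozen=True)
class Detection:
    """One positively classified window."""

    x: int
    y: int
    size: int
    frame_index: int
    label: object
    score: float

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.size / 2.0, self.y + self.size / 2.0)


@dataclass(frozen=True)
class Marker:
    """The aggregated polyp indicator of one detection group."""

    center: tuple[float, float]
    radius: float
    count: int
    mean_score: float
    frame_index: int = 0


def group_detections(detections: list[Detection], link_distance: float = float(WINDOW_SIZE)) -> list[list[Detection]]:
    """Single-linkage grouping of detections by window-center distance.

    Two detections belong to the same group if a chain of detections links
    them with consecutive center distances ≤ ``link_distance``.
    """
    if not detections:
        return []
    if len({d.frame_index for d in detections}) > 1:
        raise ValueError("group_detections expects detections of a single frame")
    centers = np.array([d.center for d in detections])
    n = len(detections)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= link_distance**2:
                parent[find(i)] = find(j)
    groups: dict[int, list[Detection]] = {}
    for i, det in enumerate(detections):
        groups.setdefault(find(i), []).append(det)
    # deterministic order: by first-detection appearance
    return sorted(groups.values(), key=lambda g: min(detections.index(d) for d in g))


def aggregate_marker(group: list[Detection], score_fraction: float = 0.8) -> Marker:
    """Average the centers of the group's high-scoring windows into a marker.

    Windows with score ≥ ``score_fraction`` × (group maximum) contribute;
    the marker center is the arithmetic mean of the kept window centers.
    """
    if not group:
        raise EmptyInputError("cannot aggregate an empty detection group")
    top = max(d.score for d in group)
    threshold = score_fraction * top if top >= 0 else top  # all-negative group: keep only the max
    kept = [d for d in group if d.score >= threshold]
    centers = np.array([d.center for d in kept])
    cx, cy = centers.mean(axis=0)
    return Marker(
        center=(float(cx), float(cy)),
        radius=kept[0].size / 2.0,
        count=len(kept),
        mean_score=float(np.mean([d.score for d in kept])),
        frame_index=group[0].frame_index,
    )


def annotate_frame(frame: Frame, markers: list[Marker], color=(0, 255, 0), thickness: int = 3) -> Frame:
    """Draw each marker as a circle; pixels off the strokes are untouched."""
    from skimage.draw import circle_perimeter

    pixels = frame.pixels.copy()
    h, w = pixels.shape[:2]
    for m in markers:
        cx, cy = m.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise BoundsError(f"marker center {m.center} outside the {w}x{h} frame")
        base = int(round(m.radius))
        for dr in range(thickness):
            rr, cc = circle_perimeter(int(round(cy)), int(round(cx)), max(1, base - dr), shape=(h, w))
            pixels[rr, cc] = color
    return Frame(index=frame.index, pixels=pixels, roi=frame.roi)


def write_annotated_video(frames: list[Frame], path, codec: str = "rawvideo", fps: int = 25) -> None:
    """Write annotated frames to a video container (lossless AVI)."""
    if not frames:
        raise EmptyInputError("no frames to write")
    if codec != "rawvideo":
        raise IOError(f"unsupported codec {codec!r}; only lossless 'rawvideo' AVI is available")
    avi.write_avi(path, [f.pixels for f in frames], fps=fps)


class PolypDetector:
    """End-to-end detector: windows → fused features → SVM → markers.

    Binds a fitted :class:`~polypscan.wavelet.ColorWaveletExtractor`, a
    fitted :class:`~polypscan.cnn.CnnFeatureExtractor` and a fitted
    :class:`~polypscan.fusion.FusedPolypClassifier`.
    """

    def __init__(
        self,
        cw_extractor,
        cnn_extractor,
        classifier,
        positive_class=1,
        stride: int = DEFAULT_STRIDE,
        score_fraction: float = 0.8,
        link_distance: float = float(WINDOW_SIZE),
    ):
        self.cw_extractor = cw_extractor
        self.cnn_extractor = cnn_extractor
        self.classifier = classifier
        self.positive_class = positive_class
        self.stride = stride
        self.score_fraction = score_fraction
        self.link_distance = link_distance

    def score_windows(self, windows: list[Window]):
        from .fusion import fuse

        cw = self.cw_extractor.transform(windows)
        cnn = self.cnn_extractor.transform(windows)
        return self.classifier.predict_with_scores(fuse(cw, cnn))

    def detect_frame(self, frame: Frame) -> list[Marker]:
        windows = generate_windows(frame, stride=self.stride)
        labels, scores = self.score_windows(windows)
        detections = [
            Detection(x=w.origin[0], y=w.origin[1], size=w.size, frame_index=w.frame_index, label=l, score=float(s))
            for w, l, s in zip(windows, labels, scores)
            if l == self.positive_class
        ]
        return [
            aggregate_marker(g, score_fraction=self.score_fraction)
            for g in group_detections(detections, link_distance=self.link_distance)
        ]

    def detect_frames(self, frames: list[Frame]) -> dict[int, list[Marker]]:
        return {f.index: self.detect_frame(f) for f in frames}

    def run(self, frames: list[Frame], out_video=None, report_path=None) -> dict[int, list[Marker]]:
        """Detect on every frame; optionally write annotated video and JSON report."""
        markers_by_frame = self.detect_frames(frames)
        if out_video is not None:
            annotated = [annotate_frame(f, markers_by_frame[f.index]) for f in frames]
            write_annotated_video(annotated, out_video)
        if report_path is not None:
            report = [
                {
                    "frame_index": fi,
                    "x": m.center[0],
                    "y": m.center[1],
                    "mean_score": m.mean_score,
                    "n_windows": m.count,
                }
                for fi in sorted(markers_by_frame)
                for m in markers_by_frame[fi]
            ]
            with open(report_path, "w") as fh:
                json.dump(report, fh, indent=2)
        return markers_by_frame

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        """Bundle CNN weights, SVM hyperplane and settings into one archive."""
        import io as _io

        from .cnn import CnnFeatureExtractor  # noqa: F401  (load-time symmetry)

        cnn_buf, svm_buf = _io.BytesIO(), _io.BytesIO()
        self.cnn_extractor.save(cnn_buf)
        self.classifier.save(svm_buf)
        meta = {
            "positive_class": self.positive_class,
            "stride": self.stride,
            "score_fraction": self.score_fraction,
            "link_distance": self.link_distance,
            "cw_params": self.cw_extractor.get_params(),
        }
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            cnn=np.frombuffer(cnn_buf.getvalue(), dtype=np.uint8),
            svm=np.frombuffer(svm_buf.getvalue(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "PolypDetector":
        import io as _io

        from .cnn import CnnFeatureExtractor
        from .fusion import FusedPolypClassifier
        from .wavelet import ColorWaveletExtractor

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cnn = CnnFeatureExtractor.load(_io.BytesIO(bytes(data["cnn"])))
            svm = FusedPolypClassifier.load(_io.BytesIO(bytes(data["svm"])))
        return cls(
            cw_extractor=ColorWaveletExtractor(**meta["cw_params"]),
            cnn_extractor=cnn,
            classifier=svm,
            positive_class=meta["positive_class"],
            stride=meta["stride"],
            score_fraction=meta["score_fraction"],
            link_distance=meta["link_distance"],
        )
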