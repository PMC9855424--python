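"""Synthetic fixtures with known ground truth for every analysis stage.

Real recordings from the wet lab (striation immunofluorescence, calcium
videos, mitochondrial dye channels) are not redistributable, so each
generator here builds a small artifact from explicit physical parameters
and returns it together with a :class:`SyntheticSpec` carrying the exact
truth the corresponding analysis is expected to recover. Every generator
is a pure function of ``(seed, params)``: identical arguments reproduce
bit-identical output.

Generated conditions follow the study protocol the analyses were built
for: ~2 µm striation periods, 0.5 Hz field-stimulated pacing sampled at
50 Hz, Fura-2 340/380 ratio pairs, skeleton-like mitochondrial networks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import morphology

from .calcium import Trace
from .sarcomere import StriationProfile

__all__ = [
    "SyntheticSpec",
    "make_striation_profile",
    "make_striation_image",
    "make_calcium_trace",
    "make_fura2_pair",
    "make_mito_image",
    "make_ros_pair",
]

KINDS = (
    "striation_profile",
    "striation_image",
    "calcium_trace",
    "fura2_pair",
    "mito_image",
    "ros_pair",
)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameter bundle and ground truth attached to a generated artifact."""

    seed: int
    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")

    def to_json(self) -> str:
        return json.dumps(_jsonable(dataclasses.asdict(self)), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        return cls(seed=d["seed"], kind=d["kind"], params=d["params"], truth=d["truth"])


# ---------------------------------------------------------------------------
# striations


def make_striation_profile(
    period_um: float,
    pixel_um: float = 0.1,
    length_um: float = 40.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    jitter_sigma: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[StriationProfile, SyntheticSpec]:
    """Periodic striation intensity profile with controllable disorder.

    ``intensity(x_i) = baseline + amplitude·cos(φ_i) + ε_i`` where the
    phase advances by ``2π·pixel_um/period_um`` per sample plus a
    cumulative Gaussian random walk with SD ``jitter_sigma`` (radians)
    per period — disorder accumulated along the fibril degrades
    long-range periodicity the way sarcomere disarray does, unlike
    i.i.d. per-pixel phase noise. ``ε ~ N(0, noise_sigma²)``.
    """
    if pixel_um <= 0:
        raise ValueError("pixel_um must be positive")
    if period_um <= 2 * pixel_um:
        raise ValueError(
            f"period {period_um} µm is at or below the Nyquist limit "
            f"{2 * pixel_um} µm for pixel size {pixel_um} µm"
        )
    if length_um < 5 * period_um:
        raise ValueError("length_um must cover at least 5 periods")
    rng = np.random.default_rng(seed)
    n = int(round(length_um / pixel_um))
    inc = 2.0 * math.pi * pixel_um / period_um
    phase = inc * np.arange(n)
    if jitter_sigma > 0:
        step_sd = jitter_sigma * math.sqrt(pixel_um / period_um)
        phase = phase + np.cumsum(rng.normal(0.0, step_sd, n))
    intensity = baseline + amplitude * np.cos(phase)
    if noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, noise_sigma, n)
    profile = StriationProfile(
        positions=np.arange(n) * pixel_um, intensities=intensity, pixel_um=pixel_um
    )
    params = dict(
        period_um=period_um,
        pixel_um=pixel_um,
        length_um=length_um,
        amplitude=amplitude,
        baseline=baseline,
        jitter_sigma=jitter_sigma,
        noise_sigma=noise_sigma,
    )
    truth = dict(
        period_um=period_um,
        amplitude=amplitude,
        jitter_sigma=jitter_sigma,
        noise_sigma=noise_sigma,
    )
    return profile, SyntheticSpec(seed=seed, kind="striation_profile", params=params, truth=truth)


def _profile_values(params: dict[str, Any], seed: int, phase_offset: float) -> np.ndarray:
    """Re-generate a striation profile's intensities with a phase offset."""
    pixel_um = params["pixel_um"]
    period_um = params["period_um"]
    n = int(round(params["length_um"] / pixel_um))
    rng = np.random.default_rng(seed)
    inc = 2.0 * math.pi * pixel_um / period_um
    phase = inc * np.arange(n) + phase_offset
    if params["jitter_sigma"] > 0:
        step_sd = params["jitter_sigma"] * math.sqrt(pixel_um / period_um)
        phase = phase + np.cumsum(rng.normal(0.0, step_sd, n))
    out = params["baseline"] + params["amplitude"] * np.cos(phase)
    if params["noise_sigma"] > 0:
        out = out + rng.normal(0.0, params["noise_sigma"], n)
    return out


def make_striation_image(
    profile_spec: SyntheticSpec,
    n_rows: int = 32,
    row_jitter_sigma: float = 0.0,
    orientation_deg: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticSpec]:
    """2-D striation image stacking phase-jittered copies of a 1-D profile.

    Each row is the base profile shifted by a per-row phase drawn from
    ``N(0, row_jitter_sigma)`` (radians); with zero jitter every row
    equals the base profile, realization noise included. ``orientation``
    0° keeps striations perpendicular to the image rows, 90° transposes
    the image exactly; other angles rotate about the image center
    (bilinear, constant fill at the baseline) and are rejected when the
    rotated profile line would leave the image bounds. The ground-truth
    line endpoints for :func:`~cardiopheno.sarcomere.profile_from_image`
    are recorded in ``truth["line_p0"]/["line_p1"]`` as (row, col)
    pixel-center coordinates.
    """
    if profile_spec.kind != "striation_profile":
        raise ValueError("profile_spec must come from make_striation_profile")
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    params = profile_spec.params
    offsets = (
        rng.normal(0.0, row_jitter_sigma, n_rows) if row_jitter_sigma > 0 else np.zeros(n_rows)
    )
    img = np.stack([_profile_values(params, profile_spec.seed, off) for off in offsets])
    n_cols = img.shape[1]
    mid = (n_rows - 1) / 2.0
    p0 = np.array([mid, 0.0])
    p1 = np.array([mid, float(n_cols - 1)])

    angle = float(orientation_deg) % 360.0
    if math.isclose(angle, 0.0, abs_tol=1e-9):
        pass
    elif math.isclose(angle, 90.0, abs_tol=1e-9):
        img = img.T
        p0, p1 = p0[::-1], p1[::-1]
    else:
        center = (np.array(img.shape, float) - 1) / 2.0
        theta = math.radians(angle)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
        )
        p0 = rot @ (p0 - center) + center
        p1 = rot @ (p1 - center) + center
        for p in (p0, p1):
            if (
                p[0] < 0
                or p[1] < 0
                or p[0] > img.shape[0] - 1
                or p[1] > img.shape[1] - 1
            ):
                raise ValueError(
                    f"orientation {orientation_deg}° rotates the profile line out of "
                    "the image bounds; increase n_rows or use a shorter profile"
                )
        img = ndimage.rotate(
            img, angle, reshape=False, order=1, mode="constant", cval=params["baseline"]
        )
    spec = SyntheticSpec(
        seed=seed,
        kind="striation_image",
        params=dict(
            profile=dict(params),
            profile_seed=profile_spec.seed,
            n_rows=n_rows,
            row_jitter_sigma=row_jitter_sigma,
            orientation_deg=orientation_deg,
        ),
        truth=dict(
            period_um=profile_spec.truth["period_um"],
            line_p0=p0.tolist(),
            line_p1=p1.tolist(),
            pixel_um=params["pixel_um"],
        ),
    )
    return img, spec


# ---------------------------------------------------------------------------
# calcium


def make_calcium_trace(
    duration_s: float = 30.0,
    fs_hz: float = 50.0,
    mode: str = "paced",
    interval_s: float = 2.0,
    interval_jitter_sd_s: float = 0.0,
    ttp_s: float = 0.2,
    tau_s: float = 0.4,
    amplitude: float = 1.0,
    diastolic: float = 1.0,
    noise_sigma: float = 0.0,
    drift_per_s: float = 0.0,
    ectopic_prob: float = 0.0,
    signal_kind: str = "raw",
    seed: int = 0,
) -> tuple[Trace, SyntheticSpec]:
    """Calcium-transient trace with known kinetics and rhythm.

    Defaults emulate the study's field-stimulation protocol: 0.5 Hz
    pacing (2 s interval) sampled at 50 Hz. Each transient rises from the
    diastolic level by ``amplitude`` over ``ttp_s`` along a half-cosine
    ramp (smooth, monotone, peak exactly at onset + ttp) and then decays
    monoexponentially with time constant ``tau_s``. Successive intervals
    are ``interval_s`` plus i.i.d. Gaussian jitter (floored at
    ``ttp_s + tau_s`` so transients can never overlap); in ``spontaneous``
    mode the rhythm model is identical but no stimulus times are recorded.
    With ``ectopic_prob > 0`` an extra mid-diastole beat is inserted with
    that per-interval probability. Optional additive Gaussian noise and a
    linear drift complete the signal. Truth records every kinetic
    parameter plus the realized onset and peak times.
    """
    if mode not in ("paced", "spontaneous"):
        raise ValueError("mode must be 'paced' or 'spontaneous'")
    if ttp_s + tau_s >= interval_s:
        raise ValueError(
            f"transients would overlap: ttp + tau = {ttp_s + tau_s:.3g} s "
            f">= interval {interval_s:.3g} s"
        )
    rng = np.random.default_rng(seed)
    min_gap = ttp_s + tau_s
    onsets: list[float] = []
    t0 = 0.0
    while t0 < duration_s - ttp_s:
        onsets.append(t0)
        gap = interval_s
        if interval_jitter_sd_s > 0:
            gap = max(min_gap, interval_s + rng.normal(0.0, interval_jitter_sd_s))
        if ectopic_prob > 0 and rng.random() < ectopic_prob and gap / 2.0 >= min_gap:
            onsets.append(t0 + gap / 2.0)
        t0 += gap

    n = int(round(duration_s * fs_hz))
    time = np.arange(n) / fs_hz
    values = np.full(n, float(diastolic))
    if drift_per_s != 0.0:
        values = values + drift_per_s * time
    onsets_arr = np.array(onsets)
    peaks_arr = onsets_arr + ttp_s
    for k, on in enumerate(onsets):
        end = onsets[k + 1] if k + 1 < len(onsets) else duration_s + 10 * tau_s
        rise = (time >= on) & (time < on + ttp_s)
        values[rise] += amplitude * 0.5 * (1.0 - np.cos(math.pi * (time[rise] - on) / ttp_s))
        dec = (time >= on + ttp_s) & (time < end)
        values[dec] += amplitude * np.exp(-(time[dec] - on - ttp_s) / tau_s)
    if noise_sigma > 0:
        values = values + rng.normal(0.0, noise_sigma, n)

    trace = Trace(time, values, signal_kind=signal_kind, name="synthetic")
    params = dict(
        duration_s=duration_s,
        fs_hz=fs_hz,
        mode=mode,
        interval_s=interval_s,
        interval_jitter_sd_s=interval_jitter_sd_s,
        ttp_s=ttp_s,
        tau_s=tau_s,
        amplitude=amplitude,
        diastolic=diastolic,
        noise_sigma=noise_sigma,
        drift_per_s=drift_per_s,
        ectopic_prob=ectopic_prob,
    )
    truth = dict(
        onset_times_s=onsets_arr.tolist(),
        peak_times_s=peaks_arr.tolist(),
        ttp_s=ttp_s,
        tau_s=tau_s,
        amplitude=amplitude,
        diastolic=diastolic,
        rate_hz=1.0 / interval_s,
    )
    if mode == "paced":
        truth["stimulus_times_s"] = onsets_arr.tolist()
    return trace, SyntheticSpec(seed=seed, kind="calcium_trace", params=params, truth=truth)


def make_fura2_pair(
    ratio_trace: Trace,
    f380_baseline: float = 1000.0,
    noise_sigma: float = 0.0,
    background: float = 0.0,
    seed: int = 0,
) -> tuple[Trace, Trace, SyntheticSpec]:
    """Paired 340/380 nm excitation channels realizing a given ratio trace.

    ``F380 = background + f380_baseline + ε``,
    ``F340 = background + ratio·f380_baseline + ε`` — so with the
    background subtracted, F340/F380 reproduces the input ratio exactly
    in the noiseless case, while an unsubtracted background biases the
    recovered ratio toward 1.
    """
    r = ratio_trace.values
    if np.any(r <= 0):
        raise ValueError("ratio trace must be strictly positive")
    if f380_baseline <= background:
        raise ValueError("f380_baseline must exceed background")
    rng = np.random.default_rng(seed)
    n = len(ratio_trace)
    f380 = np.full(n, background + f380_baseline)
    f340 = background + r * f380_baseline
    if noise_sigma > 0:
        f380 = f380 + rng.normal(0, noise_sigma, n)
        f340 = f340 + rng.normal(0, noise_sigma, n)
    t340 = Trace(ratio_trace.time_s, f340, signal_kind="raw", name=f"{ratio_trace.name}_340")
    t380 = Trace(ratio_trace.time_s, f380, signal_kind="raw", name=f"{ratio_trace.name}_380")
    spec = SyntheticSpec(
        seed=seed,
        kind="fura2_pair",
        params=dict(
            f380_baseline=f380_baseline, noise_sigma=noise_sigma, background=background
        ),
        truth=dict(ratio=r.tolist(), background=background),
    )
    return t340, t380, spec


# ---------------------------------------------------------------------------
# mitochondria / ROS

Segment = tuple[tuple[int, int], tuple[int, int]]


def _chain_length(seg: Segment) -> float:
    """Length of the 8-connected Bresenham chain drawing a segment."""
    dr = abs(seg[1][0] - seg[0][0])
    dc = abs(seg[1][1] - seg[0][1])
    return (max(dr, dc) - min(dr, dc)) + min(dr, dc) * math.sqrt(2.0)


def _split_layout(layout: Sequence[Segment]) -> list[Segment]:
    """Split segments wherever another segment's endpoint touches them.

    Lets layouts express T-junctions naturally (a crossbar ending on the
    middle of a vertical): the touched segment is cut at the contact
    point so every junction is a shared endpoint of the resulting
    segments. Mid-segment crossings without a coincident endpoint are
    not representable and will be caught by the drawn-component check.
    """
    endpoints = {p for seg in layout for p in seg}
    out: list[Segment] = []
    for a, b in layout:
        rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
        chain = list(zip(rr.tolist(), cc.tolist()))
        cuts = sorted(
            {0, len(chain) - 1}
            | {i for i in range(1, len(chain) - 1) if chain[i] in endpoints}
        )
        for i, j in zip(cuts, cuts[1:]):
            out.append((chain[i], chain[j]))
    return out


def _layout_truth(layout: Sequence[Segment]) -> dict[str, Any]:
    """Exact skeleton statistics implied by a segment layout.

    Segments are joined where they share an endpoint coordinate; a shared
    endpoint touched by >= 3 segment ends is a junction. A connected
    component with no junction is an individual, otherwise a network.
    """
    nodes: dict[tuple[int, int], int] = {}
    parent: list[int] = []

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    deg: dict[tuple[int, int], int] = {}
    seg_comp: list[int] = []
    for seg in layout:
        ids = []
        for p in seg:
            p = (int(p[0]), int(p[1]))
            if p not in nodes:
                nodes[p] = len(parent)
                parent.append(len(parent))
            deg[p] = deg.get(p, 0) + 1
            ids.append(nodes[p])
        union(ids[0], ids[1])
        seg_comp.append(ids[0])

    comp_of = {p: find(i) for p, i in nodes.items()}
    comps = sorted(set(comp_of.values()))
    junction_comps = {comp_of[p] for p, d in deg.items() if d >= 3}
    lengths = [_chain_length(s) for s in layout]
    branches_per_network = [
        sum(1 for s, i in zip(layout, seg_comp) if find(i) == c) for c in junction_comps
    ]
    return dict(
        n_individuals=len(comps) - len(junction_comps),
        n_networks=len(junction_comps),
        n_branches=len(layout),
        branches_per_network=sorted(branches_per_network),
        mean_branches_per_network=(
            float(np.mean(branches_per_network)) if branches_per_network else 0.0
        ),
        branch_lengths_px=lengths,
        total_branch_length_px=float(np.sum(lengths)),
        mean_branch_length_px=float(np.mean(lengths)),
        n_junctions=sum(1 for d in deg.values() if d >= 3),
    )


def make_mito_image(
    layout: Sequence[Segment],
    thickness_px: int = 3,
    blur_sigma_px: float = 0.0,
    noise_sigma: float = 0.0,
    intensity: float = 100.0,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, SyntheticSpec]:
    """Toy mitochondrial-network image with exact skeleton ground truth.

    ``layout`` is a list of straight segments ``((r0, c0), (r1, c1))`` in
    pixel coordinates; segments meeting at a shared endpoint form
    junctions. The skeleton is drawn, dilated to ``thickness_px``,
    optionally blurred and noised. Distinct layout components whose drawn
    masks touch are rejected (the truth would be ambiguous). Truth
    records individual/network counts, branches per network and branch
    lengths computed from the layout.
    """
    if not layout:
        raise ValueError("empty layout: at least one segment required")
    layout = [((int(a[0]), int(a[1])), (int(b[0]), int(b[1]))) for a, b in layout]
    margin = thickness_px + 2
    if shape is None:
        rmax = max(max(a[0], b[0]) for a, b in layout)
        cmax = max(max(a[1], b[1]) for a, b in layout)
        shape = (rmax + margin + 1, cmax + margin + 1)
    for a, b in layout:
        for p in (a, b):
            if not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]):
                raise ValueError(f"segment endpoint {p} outside image shape {shape}")

    split = _split_layout(layout)
    truth = _layout_truth(split)

    canvas = np.zeros(shape, dtype=bool)
    for a, b in split:
        rr, cc = skdraw.line(a[0], a[1], b[0], b[1])
        canvas[rr, cc] = True
    radius = max(0, (thickness_px - 1) // 2)
    mask = morphology.dilation(canvas, morphology.disk(radius)) if radius else canvas

    n_layout_comps = truth["n_individuals"] + truth["n_networks"]
    labeled, n_img_comps = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n_img_comps != n_layout_comps:
        raise ValueError(
            f"layout components merge or split when drawn "
            f"({n_layout_comps} in layout, {n_img_comps} in image); "
            "truth would be ambiguous — separate the segments"
        )

    rng = np.random.default_rng(seed)
    img = mask.astype(float) * intensity
    if blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, blur_sigma_px)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    truth["footprint_px"] = int(mask.sum())
    spec = SyntheticSpec(
        seed=seed,
        kind="mito_image",
        params=dict(
            layout=[list(map(list, s)) for s in layout],
            thickness_px=thickness_px,
            blur_sigma_px=blur_sigma_px,
            noise_sigma=noise_sigma,
            intensity=intensity,
            shape=list(shape),
        ),
        truth=truth,
    )
    return img, spec


def make_ros_pair(
    mask_image: np.ndarray,
    tracker_level: float = 100.0,
    sox_level: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticSpec]:
    """Paired MitoTracker / MitoSOX channels with a known intensity ratio.

    Inside the mask the tracker channel has mean ``tracker_level`` and the
    superoxide channel mean ``sox_level`` (plus optional Gaussian noise);
    truth records ``ratio = sox_level / tracker_level``.
    """
    mask = np.asarray(mask_image).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if tracker_level <= 0:
        raise ValueError("tracker_level must be positive")
    rng = np.random.default_rng(seed)
    tracker = mask * float(tracker_level)
    sox = mask * float(sox_level)
    if noise_sigma > 0:
        tracker = tracker + rng.normal(0.0, noise_sigma, mask.shape)
        sox = sox + rng.normal(0.0, noise_sigma, mask.shape)
    else:
        tracker = tracker.astype(float)
        sox = sox.astype(float)
    spec = SyntheticSpec(
        seed=seed,
        kind="ros_pair",
        params=dict(
            tracker_level=tracker_level, sox_level=sox_level, noise_sigma=noise_sigma
        ),
        truth=dict(ratio=sox_level / tracker_level, n_pixels=int(mask.sum())),
    )
    return tracker, sox, spec
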