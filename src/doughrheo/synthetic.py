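"""Synthetic inputs with known ground truth for every pipeline stage.

Instrument output for squeezing-flow, oscillatory shear, fermentation
volume tracking and network micrographs is emulated here so the full
analysis is testable end to end without any measured data.  Every
simulator is a pure function of its parameters and seed.

The squeezing-flow simulator draws stresses from the constitutive family

    sigma = C * rate**m * exp(shi_true * strain)

chosen because the strain-hardening regression cascade (log-log then
semilog lines) is exact on it: parameter recovery is then a sharp test,
not an approximation.  At fixed strain this family is also a power-law
flow curve, eta = (C e^(shi_true * strain)) * rate**(m-1), i.e.
consistency index K = C * exp(shi_true * strain) and flow index n = m.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.morphology import disk

from .fermentation import VolumeTrajectory
from .lsf import LSFTrace
from .shear import FrequencySweep
from .pna import Micrograph

__all__ = [
    "ConstitutiveParams",
    "NetworkSimSpec",
    "NetworkTruth",
    "STUDY_SPEEDS",
    "simulate_lsf_trace",
    "simulate_speed_set",
    "simulate_frequency_sweep",
    "simulate_volume_trajectory",
    "simulate_network_image",
]

#: Platen speeds (mm/s) of the five-speed squeezing-flow protocol.
STUDY_SPEEDS: tuple[float, ...] = (0.1, 1.0, 2.0, 5.0, 10.0)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=size)


@dataclass(frozen=True)
class ConstitutiveParams:
    """Parameters of the synthetic dough constitutive law.

    ``C`` (Pa) sets the stress scale, ``m`` the strain-rate exponent,
    ``shi_true`` the strain-hardening coefficient; ``noise_cv`` is the
    relative multiplicative measurement noise.  Defaults give apparent
    biaxial viscosities of order 1e4-1e6 Pa s and an SHI in the 1-3
    band typical of wheat dough.
    """

    C: float = 8000.0  # Pa
    m: float = 0.25
    shi_true: float = 2.0
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def stress(self, rate, strain):
        """Noise-free constitutive stress sigma(rate, strain) in Pa."""
        return self.C * np.asarray(rate, float) ** self.m * np.exp(
            self.shi_true * np.asarray(strain, float)
        )


def simulate_lsf_trace(
    p: ConstitutiveParams,
    v: float,
    h0: float = 20.0,
    r_p: float = 22.5,
    *,
    sample_rate: float | None = None,
    end_height: float = 2.0,
    label: str = "",
) -> LSFTrace:
    """Simulate one constant-speed squeezing-flow force trace.

    Geometry defaults follow the five-speed protocol: 45 mm diameter
    plates, compression from 20 mm down to ``end_height`` = 2 mm (90 %
    engineering deformation).  ``sample_rate`` in Hz; if omitted, 1000
    evenly spaced samples cover the stroke.  Noise is multiplicative
    lognormal with CV ``p.noise_cv``, drawn from a generator seeded by
    ``p.seed`` (same parameters -> bit-identical trace).
    """
    if v <= 0 or h0 <= end_height or end_height <= 0:
        raise ValueError("invalid squeezing-flow geometry")
    duration = (h0 - end_height) / v
    if sample_rate is None:
        t = np.linspace(0.0, duration, 1000)
    else:
        n = int(np.floor(duration * sample_rate)) + 1
        t = np.arange(n) / sample_rate
    h = h0 - v * t
    strain = 0.5 * np.log(h0 / h)
    rate = v / (2.0 * h)
    rng = np.random.default_rng(p.seed)
    sigma = p.stress(rate, strain) * _lognormal_noise(rng, p.noise_cv, t.shape)
    force = sigma * np.pi * (r_p * 1e-3) ** 2
    return LSFTrace(
        time=t,
        force=force,
        platen_speed=v,
        initial_height=h0,
        plate_radius=r_p,
        label=label or f"sim v={v:g} mm/s",
    )


def simulate_speed_set(
    p: ConstitutiveParams,
    speeds: Sequence[float] = STUDY_SPEEDS,
    h0: float = 20.0,
    r_p: float = 22.5,
    *,
    sample_rate: float | None = None,
) -> list[LSFTrace]:
    """One trace per platen speed, independently seeded from ``p.seed``."""
    seeds = np.random.SeedSequence(p.seed).spawn(len(speeds))
    traces = []
    for v, ss in zip(speeds, seeds):
        pv = ConstitutiveParams(
            C=p.C, m=p.m, shi_true=p.shi_true, noise_cv=p.noise_cv,
            seed=int(ss.generate_state(1)[0] % (2**31)),
        )
        traces.append(simulate_lsf_trace(pv, v, h0, r_p, sample_rate=sample_rate))
    return traces


def simulate_frequency_sweep(
    A_f: float,
    z: float,
    *,
    n_points: int = 20,
    noise_cv: float = 0.0,
    seed: int = 0,
    f_min: float = 0.1,
    f_max: float = 10.0,
) -> FrequencySweep:
    """Power-law complex-modulus sweep G* = A_f * (2 pi f)**(1/z).

    Frequencies are log-spaced over ``f_min``-``f_max`` Hz (the usual
    0.1-10 Hz instrument window); noise is mean-one lognormal.
    """
    if A_f <= 0 or z == 0:
        raise ValueError("need A_f > 0 and z != 0")
    f = np.logspace(np.log10(f_min), np.log10(f_max), n_points)
    rng = np.random.default_rng(seed)
    g = A_f * (2.0 * np.pi * f) ** (1.0 / z) * _lognormal_noise(rng, noise_cv, f.shape)
    return FrequencySweep(frequency=f, g_star=g, angular=False, label="simulated sweep")


def simulate_volume_trajectory(
    model: str,
    t_grid: Sequence[float],
    *,
    k: float = 5e-4,
    v_max: float = 4.0,
    rate: float = 2e-3,
    t_mid: float = 1800.0,
) -> VolumeTrajectory:
    """Relative-volume trajectory under exponential or logistic gas growth.

    ``model='exponential'``: V_rel = exp(k t) (constant Bloksma rate k);
    ``model='logistic'``: V_rel = 1 + (v_max - 1)/(1 + exp(-rate (t - t_mid))),
    a proofing-like rise to a plateau.  Defaults sit in the 1e-4 to
    1e-3 1/s strain-rate decade typical of proofing dough.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if model == "exponential":
        if k < 0:
            raise ValueError("growth constant k must be >= 0")
        v = np.exp(k * t)
    elif model == "logistic":
        if v_max < 1:
            raise ValueError("v_max must be >= 1")
        v = 1.0 + (v_max - 1.0) / (1.0 + np.exp(-rate * (t - t_mid)))
    else:
        raise ValueError(f"unknown model {model!r}")
    return VolumeTrajectory(time=t, v_rel=v, label=f"sim {model}")


# ---------------------------------------------------------------------------
# branched strand network images


@dataclass(frozen=True)
class NetworkSimSpec:
    """Geometry of a simulated branched strand network image.

    Strands are trees of straight segments on the 8 compass directions,
    grown with a minimum-separation constraint so the rasterised image
    is unambiguous: thresholding and skeletonising it recovers exactly
    the recorded junction and endpoint counts.
    """

    size: int = 256
    pixel_size: float = 0.22  # um / px
    n_strands: int = 6
    strand_width: int = 3  # px, odd
    branching_prob: float = 0.45
    noise_sigma: float = 8.0  # grayscale units on a 30/200 bg/fg image
    seg_len: tuple[int, int] = (16, 30)  # px, inclusive range
    max_segments: int = 12  # per strand
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64 or self.n_strands < 1:
            raise ValueError("image too small or no strands requested")
        if self.strand_width < 1 or self.strand_width % 2 == 0:
            raise ValueError("strand width must be a positive odd pixel count")
        if not (0 <= self.branching_prob <= 1):
            raise ValueError("branching probability must be in [0, 1]")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")


@dataclass(frozen=True)
class NetworkTruth:
    """Ground truth recorded while growing a synthetic network."""

    junction_count: int
    endpoint_count: int
    total_length: float  # um, Euclidean over segments
    mask: np.ndarray = field(repr=False)  # noise-free foreground mask
    n_strands_placed: int = 0
    node_degrees: dict = field(default_factory=dict, repr=False)  # (row, col) -> degree


_DIRS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)  # 8 compass directions, 45 deg apart

_DIR_INDEX = {(int(d[0]), int(d[1])): i for i, d in enumerate(_DIRS)}


def _dir_index(p: tuple[int, int], q: tuple[int, int]) -> int:
    return _DIR_INDEX[(int(np.sign(q[0] - p[0])), int(np.sign(q[1] - p[1])))]


def simulate_network_image(spec: NetworkSimSpec) -> tuple[Micrograph, NetworkTruth]:
    """Grow branched strand trees and rasterise them into a micrograph.

    Each strand is a tree of straight segments; branches leave the trunk
    at +-90 deg and the trunk may turn by +-45 deg between segments.
    Segments are only accepted if they keep a clearance margin from all
    previously drawn material (except around their own start node), so
    strands never touch and corners stay crisp.  Strand placement that
    fails after bounded retries simply yields fewer strands; the truth
    reflects what was actually drawn.

    Returns the noisy grayscale image and a :class:`NetworkTruth` with
    the exact junction/endpoint counts and the noise-free mask.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    half_w = spec.strand_width // 2
    clearance = spec.strand_width + 3  # min centreline separation enforcement
    excl_r = clearance + 2  # self-overlap allowance around a segment's start
    border = half_w + 4

    centre = np.zeros((size, size), dtype=bool)  # 1-px centrelines
    occupancy = np.zeros((size, size), dtype=bool)  # centrelines dilated by clearance
    clear_stamp = disk(clearance).astype(bool)
    yy, xx = np.mgrid[0:size, 0:size]

    node_degree: dict[tuple[int, int], int] = {}
    node_dirs: dict[tuple[int, int], set[int]] = {}  # outgoing directions per node
    total_length_px = 0.0

    def direction_free(p: tuple[int, int], nd: int) -> bool:
        # segments sharing a node must be >= 90 deg apart, otherwise their
        # rasterised ribbons merge into a blob the skeleton misreads
        for e in node_dirs.get(p, ()):
            if min((nd - e) % 8, (e - nd) % 8) < 2:
                return False
        return True

    def segment_ok(p: tuple[int, int], q: tuple[int, int]) -> bool:
        if not (border <= q[0] < size - border and border <= q[1] < size - border):
            return False
        rr, cc = _draw_line(p[0], p[1], q[0], q[1])
        hits = occupancy[rr, cc]
        if not hits.any():
            return True
        # overlap is only tolerated right around the shared start node
        d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
        return bool(np.all(d2[hits] <= excl_r**2))

    def stamp(p: tuple[int, int], q: tuple[int, int]) -> None:
        nonlocal total_length_px
        rr, cc = _draw_line(p[0], p[1], q[0], q[1])
        centre[rr, cc] = True
        seg = np.zeros((size, size), dtype=bool)
        seg[rr, cc] = True
        occupancy[:] |= ndimage.binary_dilation(seg, structure=clear_stamp)
        total_length_px += float(np.hypot(q[0] - p[0], q[1] - p[1]))
        node_degree[p] = node_degree.get(p, 0) + 1
        node_degree[q] = node_degree.get(q, 0) + 1
        nd = _dir_index(p, q)
        node_dirs.setdefault(p, set()).add(nd)
        node_dirs.setdefault(q, set()).add((nd + 4) % 8)

    placed = 0
    for _ in range(spec.n_strands):
        root = None
        for _attempt in range(40):
            cand = (
                int(rng.integers(border, size - border)),
                int(rng.integers(border, size - border)),
            )
            if not occupancy[cand]:
                # require free space around the root too
                d2 = (yy - cand[0]) ** 2 + (xx - cand[1]) ** 2
                if not occupancy[d2 <= excl_r**2].any():
                    root = cand
                    break
        if root is None:
            continue
        d0 = int(rng.integers(0, 8))
        tips = [(root, d0)]
        n_seg = 0
        grown = False
        while tips and n_seg < spec.max_segments:
            pos, d = tips.pop(0)
            length = int(rng.integers(spec.seg_len[0], spec.seg_len[1] + 1))
            # try straight-ish continuations until one fits
            accepted = None
            for turn in rng.permutation([0, 1, -1]):
                nd = (d + turn) % 8
                if not direction_free(pos, nd):
                    continue
                step = _DIRS[nd]
                q = (pos[0] + int(step[0]) * length, pos[1] + int(step[1]) * length)
                if segment_ok(pos, q):
                    accepted = (q, nd)
                    break
            if accepted is None:
                continue
            q, nd = accepted
            stamp(pos, q)
            grown = True
            n_seg += 1
            # trunk continues; branch at +-90 deg with the given probability
            tips.append((q, nd))
            if rng.random() < spec.branching_prob:
                tips.append((q, (nd + int(rng.choice([-2, 2]))) % 8))
        if grown:
            placed += 1

    junctions = sum(1 for deg in node_degree.values() if deg >= 3)
    endpoints = sum(1 for deg in node_degree.values() if deg == 1)

    mask = (
        ndimage.binary_dilation(centre, structure=disk(half_w)) if half_w else centre.copy()
    )
    img = np.where(mask, 200.0, 30.0)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    truth = NetworkTruth(
        junction_count=junctions,
        endpoint_count=endpoints,
        total_length=total_length_px * spec.pixel_size,
        mask=mask,
        n_strands_placed=placed,
        node_degrees=dict(node_degree),
    )
    return Micrograph(data=img, pixel_size=spec.pixel_size, label="simulated network"), truth
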