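"""Seeded synthetic-data generators with paired ground truth.

Every generator emulates one input modality of the nuclear-mechanics
pipeline — multichannel nucleus images (DAPI / lamin B1 / γH2AX), comet
assay images, square-wave optical-tweezers indentation traces, AFM
approach curves, gel-lane digestion profiles — and returns the rendered
artifact together with a :class:`SyntheticTruth` holding the generating
parameters, so every downstream stage can be tested against known truth.

Noise is additive Gaussian throughout (a Poisson option exists for
images). Identical seeds produce bit-identical outputs; a single global
seed fans out into independent per-generator streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .afm import AfmCurve, _hertz_coef_nN_per_nm15
from .core import ForceTrace, Image2D, IndentationProtocol, LabeledMask
from .ot import g_master, hertz_force

__all__ = [
    "SyntheticTruth",
    "stream_rng",
    "make_nucleus_image",
    "make_comet_image",
    "make_ot_trace",
    "make_afm_curve",
    "make_digestion_profile",
]


@dataclass
class SyntheticTruth:
    """Generator-side ground truth paired with one synthetic artifact."""

    seed: int
    true_masks: LabeledMask | None = None
    foci_xy: list = field(default_factory=list)
    true_area_um2: list = field(default_factory=list)
    true_profile_class: list = field(default_factory=list)
    true_E_pa: float | None = None
    true_Dp_um2_per_s: float | None = None
    true_tail_fraction: float | None = None
    true_tail_length_um: float | None = None
    true_head_center_xy: tuple | None = None
    true_head_radius_um: float | None = None
    true_peak_position: int | None = None
    true_contact_z_nm: float | None = None
    extras: dict = field(default_factory=dict)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent RNG stream derived from a global seed and a stream name."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(stream.encode()),))
    )


def _finalize_channel(img: np.ndarray, noise_sd: float, rng, poisson: bool) -> np.ndarray:
    """Add background offset + noise; intensities stay non-negative."""
    out = img.astype(np.float64)
    if poisson:
        # photon-counting shot noise on a scaled signal
        out = rng.poisson(np.clip(out, 0, None) * 100.0) / 100.0
    if noise_sd > 0:
        out = out + 3.0 * noise_sd + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Nucleus images
# ---------------------------------------------------------------------------

def _nucleus_mask(
    yy, xx, cy, cx, a_px, b_px, theta, lobe_amps, lobe_phases
) -> np.ndarray:
    """Boolean mask of one (optionally lobed) elliptical nucleus.

    The boundary is r(phi) = 1 + sum_k eps_k cos(k*phi + phase_k) in the
    ellipse-normalised radial coordinate (low-order Fourier perturbation).
    """
    dy = yy - cy
    dx = xx - cx
    u = (np.cos(theta) * dx + np.sin(theta) * dy) / a_px
    v = (-np.sin(theta) * dx + np.cos(theta) * dy) / b_px
    rho = np.hypot(u, v)
    if lobe_amps:
        phi = np.arctan2(v, u)
        bound = np.ones_like(rho)
        for k, (eps, ph) in enumerate(zip(lobe_amps, lobe_phases), start=2):
            bound += eps * np.cos(k * phi + ph)
        return rho <= bound
    return rho <= 1.0


def make_nucleus_image(
    n_nuclei: int = 5,
    shape_mode: str = "ellipse",
    lamin_mode: str = "peripheral",
    n_foci: int = 0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.1,
    seed: int = 0,
    image_shape: tuple[int, int] = (512, 512),
    radius_um: tuple[float, float] = (3.2, 4.5),
    shell_thickness_um: float = 0.4,
    focus_sigma_um: float = 0.25,
    poisson: bool = False,
    allow_overlap: bool = False,
    max_retries: int = 400,
) -> tuple[dict[str, Image2D], SyntheticTruth]:
    """Render a 3-channel nucleus field with paired ground truth.

    Channels: ``DAPI`` (filled nuclei), ``laminB1`` (peripheral shell, or
    shell plus 2–4 internal fold lines and a multilobed boundary when
    ``lamin_mode='aberrant'``), ``gH2AX`` (``n_foci`` Gaussian puncta per
    nucleus inside the mask). Nuclei are placed without overlap unless
    ``allow_overlap``; placement failure after bounded retries raises.
    """
    if n_nuclei < 0 or noise_sd < 0:
        raise ValueError("n_nuclei and noise_sd must be non-negative")
    if shape_mode not in ("ellipse", "lobed"):
        raise ValueError(f"unknown shape_mode {shape_mode!r}")
    if lamin_mode not in ("peripheral", "aberrant"):
        raise ValueError(f"unknown lamin_mode {lamin_mode!r}")
    rng = stream_rng(seed, "nucleus_image")
    H, W = image_shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    labels = np.zeros((H, W), dtype=np.int64)
    dapi = np.zeros((H, W))
    lamin = np.zeros((H, W))
    foci_ch = np.zeros((H, W))
    foci_xy: list[tuple[float, float]] = []
    classes: list[str] = []
    areas: list[float] = []

    lobed = shape_mode == "lobed" or lamin_mode == "aberrant"
    margin_px = radius_um[1] / pixel_size_um * (1.5 if lobed else 1.2) + 4

    placed = 0
    for k in range(1, n_nuclei + 1):
        for attempt in range(max_retries):
            a_um = rng.uniform(*radius_um)
            b_um = a_um * rng.uniform(0.6, 0.9)
            a_px, b_px = a_um / pixel_size_um, b_um / pixel_size_um
            theta = rng.uniform(0, np.pi)
            cy = rng.uniform(margin_px, H - margin_px)
            cx = rng.uniform(margin_px, W - margin_px)
            if lobed:
                n_lobes = rng.integers(2, 4)  # Fourier orders 2..(2+n-1)
                lobe_amps = list(rng.uniform(0.08, 0.16, size=n_lobes))
                lobe_phases = list(rng.uniform(0, 2 * np.pi, size=n_lobes))
            else:
                lobe_amps, lobe_phases = [], []
            mask = _nucleus_mask(yy, xx, cy, cx, a_px, b_px, theta, lobe_amps, lobe_phases)
            if not mask.any():
                continue
            grown = ndimage.binary_dilation(mask, iterations=3)
            if allow_overlap or not np.any(labels[grown] > 0):
                break
        else:
            raise RuntimeError(
                f"could not place nucleus {k} without overlap after {max_retries} retries"
            )
        labels[mask] = k
        dapi[mask] = 1.0
        areas.append(float(mask.sum()) * pixel_size_um**2)

        # lamin shell: thin band inside the boundary
        dist_in = ndimage.distance_transform_edt(mask)
        shell_px = shell_thickness_um / pixel_size_um
        shell = mask & (dist_in <= shell_px)
        lamin[shell] = 1.0
        if lamin_mode == "aberrant":
            # 2-4 internal fold lines crossing the interior; the first passes
            # through the centroid at 30-150 deg to the major axis so a
            # transversal profile along the major axis always crosses a fold
            n_folds = int(rng.integers(2, 5))
            interior = mask & (dist_in > shell_px)
            for fi in range(n_folds):
                if fi == 0:
                    py, px_ = cy, cx
                    ang = theta + rng.uniform(np.pi / 6, 5 * np.pi / 6)
                else:
                    py = cy + rng.uniform(-0.4, 0.4) * b_px
                    px_ = cx + rng.uniform(-0.4, 0.4) * a_px
                    ang = rng.uniform(0, np.pi)
                # signed distance of each pixel to the fold line
                d = np.abs(
                    -np.sin(ang) * (xx - px_) + np.cos(ang) * (yy - py)
                )
                fold = interior & (d <= shell_px / 2.0)
                lamin[fold] = 1.0
            classes.append("aberrant")
        else:
            classes.append("peripheral")

        # gH2AX foci: well-separated Gaussian puncta inside the eroded mask
        if n_foci > 0:
            erode_px = int(np.ceil(4 * focus_sigma_um / pixel_size_um))
            inner = ndimage.binary_erosion(mask, iterations=max(erode_px, 1))
            cand_y, cand_x = np.nonzero(inner if inner.any() else mask)
            min_sep_px = 5.0 * focus_sigma_um / pixel_size_um
            chosen: list[tuple[float, float]] = []
            tries = 0
            while len(chosen) < n_foci and tries < max_retries:
                tries += 1
                i = rng.integers(len(cand_y))
                fy, fx = float(cand_y[i]), float(cand_x[i])
                if all(np.hypot(fy - oy, fx - ox) >= min_sep_px for oy, ox in chosen):
                    chosen.append((fy, fx))
            if len(chosen) < n_foci:
                raise RuntimeError("could not place well-separated foci; reduce n_foci")
            sig_px = focus_sigma_um / pixel_size_um
            for fy, fx in chosen:
                r2 = (yy - fy) ** 2 + (xx - fx) ** 2
                foci_ch += np.exp(-r2 / (2 * sig_px**2))
                foci_xy.append((fx, fy))
        placed += 1

    channels = {
        "DAPI": Image2D(_finalize_channel(dapi, noise_sd, rng, poisson), pixel_size_um, "DAPI"),
        "laminB1": Image2D(
            _finalize_channel(lamin, noise_sd, rng, poisson), pixel_size_um, "laminB1"
        ),
        "gH2AX": Image2D(
            _finalize_channel(foci_ch, noise_sd, rng, poisson), pixel_size_um, "gH2AX"
        ),
    }
    truth = SyntheticTruth(
        seed=seed,
        true_masks=LabeledMask(labels),
        foci_xy=foci_xy,
        true_area_um2=areas,
        true_profile_class=classes,
        extras={"n_foci_per_nucleus": n_foci, "lamin_mode": lamin_mode},
    )
    return channels, truth


# ---------------------------------------------------------------------------
# Comet images
# ---------------------------------------------------------------------------

def make_comet_image(
    tail_fraction: float = 0.3,
    tail_length_um: float = 20.0,
    head_radius_um: float = 5.0,
    noise_sd: float = 0.0,
    pixel_size_um: float = 0.5,
    seed: int = 0,
    image_shape: tuple[int, int] = (96, 160),
    total_intensity: float = 1000.0,
    head_center: tuple[float, float] | None = None,
) -> tuple[Image2D, SyntheticTruth]:
    """Render a single comet: bright head disk + exponentially decaying tail.

    Total noiseless intensity is split head:(1-tail_fraction) /
    tail:tail_fraction exactly; the tail decays exponentially along +x
    from the head's trailing edge with decay length ``tail_length_um / 3``
    and is truncated at ``tail_length_um``.
    """
    if not 0.0 <= tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in [0, 1]")
    if tail_length_um <= 0 or head_radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dimensional parameters must be positive")
    rng = stream_rng(seed, "comet_image")
    H, W = image_shape
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    r_px = head_radius_um / pixel_size_um
    if head_center is None:
        cy, cx = H / 2.0, r_px + 4.0
    else:
        cy, cx = head_center
    head = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    img = np.zeros((H, W))
    if head.sum() == 0:
        raise ValueError("head disk fell outside the image")
    img[head] = (1.0 - tail_fraction) * total_intensity / head.sum()

    if tail_fraction > 0:
        edge = cx + r_px
        L_px = tail_length_um / pixel_size_um
        lam_px = L_px / 3.0
        x_rel = xx - edge
        in_tail = (x_rel > 0) & (x_rel <= L_px) & ~head
        sigma_y = r_px / 2.0
        tail_field = np.where(
            in_tail,
            np.exp(-x_rel / lam_px) * np.exp(-((yy - cy) ** 2) / (2 * sigma_y**2)),
            0.0,
        )
        s = tail_field.sum()
        if s <= 0:
            raise ValueError("tail fell outside the image; enlarge image_shape")
        img += tail_field * (tail_fraction * total_intensity / s)

    pixels = _finalize_channel(img, noise_sd, rng, poisson=False)
    truth = SyntheticTruth(
        seed=seed,
        true_tail_fraction=float(tail_fraction),
        true_tail_length_um=float(tail_length_um),
        true_head_center_xy=(float(cx), float(cy)),
        true_head_radius_um=float(head_radius_um),
        extras={"total_intensity": total_intensity},
    )
    return Image2D(pixels, pixel_size_um, "comet"), truth


# ---------------------------------------------------------------------------
# Optical-tweezers traces
# ---------------------------------------------------------------------------

def make_ot_trace(
    true_E_pa: float = 1000.0,
    true_Dp_um2_per_s: float = 10.0,
    protocol: IndentationProtocol | None = None,
    noise_sd_pN: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 500.0,
    drained_poisson: float = 0.3,
) -> tuple[ForceTrace, SyntheticTruth]:
    """Simulate a square-wave amplitude-sweep indentation force trace.

    Each push half-cycle jumps to the Hertzian instantaneous peak
    F0(delta) and relaxes along F(t) = Finf + (F0 - Finf) * g(Dp*t/a**2)
    with contact radius a = sqrt(R*delta); the equilibrium plateau follows
    the drained-limit ratio Finf = F0 / (2*(1 - drained_poisson)). Retract
    half-cycles sit at force zero. Gaussian noise of SD ``noise_sd_pN`` is
    added to every sample.
    """
    if true_E_pa <= 0 or true_Dp_um2_per_s <= 0:
        raise ValueError("E and Dp must be positive")
    protocol = protocol or IndentationProtocol()
    period = 1.0 / protocol.frequency_hz
    if protocol.dwell_per_amplitude_s < 2 * period:
        raise ValueError("dwell too short: need >= 2 full cycles per amplitude")
    rng = stream_rng(seed, "ot_trace")
    rate = sample_rate_hz
    n_total = int(round(protocol.total_duration_s * rate))
    t = np.arange(n_total) / rate
    dwell = protocol.dwell_per_amplitude_s
    push_dur = period * protocol.offset_fraction / 2.0
    R = protocol.bead_radius_um

    block = np.minimum((t / dwell).astype(int), protocol.n_amplitudes - 1)
    amps = np.asarray(protocol.amplitudes_um)[block]
    phase = (t - block * dwell) % period
    in_push = phase < push_dur

    F0 = hertz_force(amps, true_E_pa, R, nu=0.5)
    Finf = F0 / (2.0 * (1.0 - drained_poisson))
    a2 = R * amps  # contact radius squared
    tau = true_Dp_um2_per_s * phase / a2
    force = np.where(in_push, Finf + (F0 - Finf) * g_master(np.clip(tau, 0, None)), 0.0)
    position = np.where(in_push, amps, 0.0)
    if noise_sd_pN > 0:
        force = force + rng.normal(0.0, noise_sd_pN, size=force.shape)
    trace = ForceTrace(
        time_s=t, force_pN=force, sample_rate_hz=rate, position_um=position
    )
    f0_table = {float(a): float(hertz_force(a, true_E_pa, R, 0.5)) for a in protocol.amplitudes_um}
    truth = SyntheticTruth(
        seed=seed,
        true_E_pa=float(true_E_pa),
        true_Dp_um2_per_s=float(true_Dp_um2_per_s),
        extras={
            "F0_pN_by_amplitude": f0_table,
            "drained_poisson": drained_poisson,
            "noise_sd_pN": noise_sd_pN,
        },
    )
    return trace, truth


# ---------------------------------------------------------------------------
# AFM approach curves
# ---------------------------------------------------------------------------

def make_afm_curve(
    true_E_pa: float = 1000.0,
    contact_z_nm: float = 500.0,
    max_force_nN: float = 0.3,
    tip_radius_nm: float = 1000.0,
    noise_sd_nN: float = 0.0,
    seed: int = 0,
    dz_nm: float = 1.0,
    nu: float = 0.5,
) -> tuple[AfmCurve, SyntheticTruth]:
    """Simulate one AFM approach curve: flat baseline then Hertzian rise,
    truncated at ``max_force_nN`` (0.3 nN is the standard PeakForce
    setpoint for isolated nuclei).
    """
    if min(true_E_pa, contact_z_nm, max_force_nN, tip_radius_nm, dz_nm) <= 0:
        raise ValueError("all physical parameters must be positive")
    rng = stream_rng(seed, "afm_curve")
    k = _hertz_coef_nN_per_nm15(true_E_pa, tip_radius_nm, nu)
    depth_max_nm = (max_force_nN / k) ** (2.0 / 3.0)
    z = np.arange(0.0, contact_z_nm + depth_max_nm + dz_nm, dz_nm)
    depth = np.clip(z - contact_z_nm, 0.0, None)
    force = np.minimum(k * depth**1.5, max_force_nN)
    if noise_sd_nN > 0:
        force = force + rng.normal(0.0, noise_sd_nN, size=force.shape)
    curve = AfmCurve(z_nm=z, force_nN=force, tip_radius_nm=tip_radius_nm, max_force_nN=max_force_nN)
    truth = SyntheticTruth(
        seed=seed,
        true_E_pa=float(true_E_pa),
        true_contact_z_nm=float(contact_z_nm),
        extras={"nu": nu, "noise_sd_nN": noise_sd_nN},
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Digestion lane profiles
# ---------------------------------------------------------------------------

def make_digestion_profile(
    peak_position: int = 300,
    peak_width: float = 40.0,
    second_peak: tuple[int, float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    length: int = 1000,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Simulate a gel-lane densitometry profile: one or two Gaussian bands
    plus noise. ``second_peak`` is ``(position, width, amplitude)``. Truth
    records the argmax position of the noiseless profile.
    """
    if not 0 <= peak_position < length:
        raise ValueError("peak_position outside profile support")
    rng = stream_rng(seed, "digestion_profile")
    x = np.arange(length, dtype=float)
    prof = amplitude * np.exp(-((x - peak_position) ** 2) / (2 * peak_width**2))
    if second_peak is not None:
        p2, w2, a2 = second_peak
        if not 0 <= p2 < length:
            raise ValueError("second peak outside profile support")
        prof = prof + a2 * np.exp(-((x - p2) ** 2) / (2 * w2**2))
    true_peak = int(np.argmax(prof))
    if noise_sd > 0:
        prof = np.clip(prof + 3.0 * noise_sd + rng.normal(0.0, noise_sd, size=length), 0.0, None)
    truth = SyntheticTruth(seed=seed, true_peak_position=true_peak)
    return prof, truth
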