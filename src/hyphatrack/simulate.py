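"""Synthetic single-mycelium growth and scattered-light signal generator.

The generator emulates the growth of a single *Streptomyces*-like spore in
a 90 x 40 um monolayer chamber:

* the spore germinates after a truncated-normal delay (with a configurable
  germination probability — non-germinating spores stay empty);
* the primary hypha elongates with a saturating-exponential rate ramp
  ``v(t) = v_inf * (1 - exp(-(t - t_birth)/tau))``, i.e. the tip speeds up
  over the first hours and approaches a constant rate;
* every later branch elongates at a constant rate drawn from a truncated
  normal distribution;
* a new lateral branch is spawned, anchored uniformly along the existing
  mycelium, whenever total length per growing tip exceeds the target
  hyphal growth unit (HGU) — which makes total length grow asymptotically
  exponentially with rate ~ mean_tip_rate / HGU;
* tips keep a persistent direction with angular noise and steer away
  from occupied space and from the chamber walls (monolayer volume
  exclusion); with avoidance disabled they instead reflect specularly
  or slide along walls.

Everything the analysis pipeline is supposed to recover (germination time,
per-tip rates, branching events, the length/tip-count series and the
implied specific growth rate) is recorded in :class:`GroundTruth`.

The same module generates bare exponential length curves and
microtiter-plate scattered-light signals (lag, exponential phase, smooth
saturation) for testing the curve-fitting stages in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import TimeLapseStack

# --------------------------------------------------------------------------
# parameters


@dataclass
class SimulationParams:
    """Knobs of the geometric mycelium simulator (lengths um, times h)."""

    chamber_width_um: float = 90.0
    chamber_height_um: float = 40.0
    pixel_size_um: float = 0.1
    frame_interval_h: float = 0.5
    n_frames: int = 60
    germination_prob: float = 1.0
    germ_delay_mean_h: float = 10.0
    germ_delay_sd_h: float = 2.4
    tip_rate_mean_um_h: float = 14.1
    tip_rate_sd_um_h: float = 6.1
    primary_accel_tau_h: float = 2.0
    target_hgu_um: float = 28.7
    angle_noise_rad: float = 0.15
    hypha_width_um: float = 0.7
    noise_sd: float = 8.0
    seed: int = 0
    sim_dt_h: float = 0.02
    max_total_length_um: float | None = None  # default: half-full chamber
    tip_avoidance: bool = True                # negative autotropism
    avoidance_grid_um: float = 1.0
    avoidance_lookahead_um: float = 1.0

    def validate(self) -> None:
        positive = [
            self.chamber_width_um, self.chamber_height_um, self.pixel_size_um,
            self.frame_interval_h, self.n_frames, self.germ_delay_mean_h,
            self.germ_delay_sd_h, self.tip_rate_mean_um_h,
            self.primary_accel_tau_h, self.target_hgu_um,
            self.hypha_width_um, self.sim_dt_h,
        ]
        if any(v <= 0 for v in positive):
            raise ValueError("all rates/lengths/intervals must be strictly positive")
        if self.tip_rate_sd_um_h < 0 or self.angle_noise_rad < 0 or self.noise_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if not 0.0 <= self.germination_prob <= 1.0:
            raise ValueError("germination_prob must lie in [0, 1]")
        horizon = self.frame_interval_h * self.n_frames
        if self.germination_prob > 0 and horizon < (
            self.germ_delay_mean_h + 3.0 * self.germ_delay_sd_h
        ):
            raise ValueError(
                "time horizon must cover germ_delay_mean_h + 3*germ_delay_sd_h"
            )

    @property
    def timestamps_h(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_h


@dataclass
class TipRecord:
    """Ground-truth record of one hyphal tip."""

    tip_id: int
    parent_id: int | None
    birth_time_h: float
    anchor_um: tuple[float, float]
    rate_um_h: float            # asymptotic rate for the primary, constant otherwise
    is_primary: bool
    ramp_tau_h: float | None = None


@dataclass
class GroundTruth:
    """Everything the pipeline is expected to recover from the images."""

    germinated: bool
    germination_time_h: float | None
    tips: list[TipRecord]
    branch_events: list[tuple[float, tuple[float, float]]]
    target_hgu_um: float
    times_h: np.ndarray
    total_length_um: np.ndarray
    tip_count: np.ndarray
    implied_mu_h: float


# --------------------------------------------------------------------------
# geometric growth simulation


class _Tip:
    __slots__ = ("record", "pos", "angle", "times", "verts", "length")

    def __init__(self, record: TipRecord, pos: np.ndarray, angle: float):
        self.record = record
        self.pos = pos.copy()
        self.angle = angle
        self.times = [record.birth_time_h]
        self.verts = [pos.copy()]
        self.length = 0.0

    def rate_at(self, t: float) -> float:
        r = self.record
        if r.is_primary and r.ramp_tau_h is not None:
            dt = max(0.0, t - r.birth_time_h)
            return r.rate_um_h * (1.0 - math.exp(-dt / r.ramp_tau_h))
        return r.rate_um_h

    def step_length(self, t0: float, t1: float) -> float:
        """Exact arc length laid down in [t0, t1] (clipped at birth)."""
        r = self.record
        a = max(t0, r.birth_time_h)
        if a >= t1:
            return 0.0
        if r.is_primary and r.ramp_tau_h is not None:
            tau = r.ramp_tau_h
            e0 = math.exp(-(a - r.birth_time_h) / tau)
            e1 = math.exp(-(t1 - r.birth_time_h) / tau)
            return r.rate_um_h * ((t1 - a) - tau * (e0 - e1))
        return r.rate_um_h * (t1 - a)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0) -> float:
    """Normal(mean, sd) conditioned on > low, by rejection."""
    if sd == 0:
        return max(mean, low)
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise RuntimeError("truncated normal rejection failed; check parameters")


def _reflect(pos: np.ndarray, angle: float, width: float, height: float
             ) -> tuple[np.ndarray, float, bool]:
    """Specular reflection of a point/direction at the chamber rectangle."""
    x, y = pos
    dx, dy = math.cos(angle), math.sin(angle)
    hit = False
    for _ in range(8):
        moved = False
        if x < 0:
            x, dx, moved = -x, -dx, True
        elif x > width:
            x, dx, moved = 2 * width - x, -dx, True
        if y < 0:
            y, dy, moved = -y, -dy, True
        elif y > height:
            y, dy, moved = 2 * height - y, -dy, True
        hit = hit or moved
        if not moved:
            break
    return np.array([x, y]), math.atan2(dy, dx), hit


def _slide(pos: np.ndarray, angle: float, ds: float, width: float,
           height: float) -> tuple[list[np.ndarray], float, bool]:
    """Advance ``ds`` um, sliding along chamber walls on contact.

    Hyphae meeting a PDMS wall follow it (wall-guided growth) rather
    than bouncing.  Returns the way-points laid down (wall contact point
    plus final position when a wall was met), the outgoing direction and
    a wall-hit flag.  Total path length equals ``ds`` except in a corner,
    where the remainder is forfeited (the tip jams).
    """
    u = np.array([math.cos(angle), math.sin(angle)])
    new = pos + ds * u
    if 0.0 <= new[0] <= width and 0.0 <= new[1] <= height:
        return [new], angle, False
    # first wall crossing along the segment
    t_hit = 1.0
    wall_axis = -1
    for axis, lim in ((0, width), (1, height)):
        if u[axis] < 0 and new[axis] < 0:
            tc = pos[axis] / -(u[axis] * ds)
        elif u[axis] > 0 and new[axis] > lim:
            tc = (lim - pos[axis]) / (u[axis] * ds)
        else:
            continue
        if tc < t_hit:
            t_hit, wall_axis = tc, axis
    contact = pos + max(t_hit, 0.0) * ds * u
    contact = np.clip(contact, [0.0, 0.0], [width, height])
    tangent = u.copy()
    tangent[wall_axis] = 0.0
    norm = float(np.hypot(*tangent))
    remainder = (1.0 - max(t_hit, 0.0)) * ds
    if norm < 1e-9 or remainder <= 0:
        return [contact], angle, True   # head-on: jam at the wall
    tangent /= norm
    final = contact + remainder * tangent
    final = np.clip(final, [0.0, 0.0], [width, height])   # corner clamp
    return [contact, final], math.atan2(tangent[1], tangent[0]), True


def simulate_mycelium(params: SimulationParams
                      ) -> tuple[list[list[np.ndarray]], GroundTruth]:
    """Grow one synthetic mycelium and return per-frame geometry + truth.

    Returns
    -------
    geometry : list over frames of lists of (N, 2) float arrays
        One polyline per hypha, in micrometres, chamber coordinates
        (x along the 90 um axis).  Tip order is stable across frames and
        each frame's polyline is a prefix (plus interpolated end point) of
        the next frame's.
    truth : GroundTruth
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    times = params.timestamps_h
    horizon = float(times[-1])

    germinated = bool(rng.random() < params.germination_prob)
    n = params.n_frames
    if not germinated:
        truth = GroundTruth(
            germinated=False, germination_time_h=None, tips=[],
            branch_events=[], target_hgu_um=params.target_hgu_um,
            times_h=times, total_length_um=np.zeros(n),
            tip_count=np.zeros(n, dtype=int),
            implied_mu_h=params.tip_rate_mean_um_h / params.target_hgu_um,
        )
        return [[] for _ in range(n)], truth

    t_g = _truncated_normal(rng, params.germ_delay_mean_h, params.germ_delay_sd_h)
    w, h = params.chamber_width_um, params.chamber_height_um
    spore = np.array([
        w / 2 + rng.uniform(-0.2, 0.2) * w / 2,
        h / 2 + rng.uniform(-0.4, 0.4) * h / 2,
    ])

    primary = TipRecord(
        tip_id=0, parent_id=None, birth_time_h=t_g,
        anchor_um=(float(spore[0]), float(spore[1])),
        rate_um_h=_truncated_normal(rng, params.tip_rate_mean_um_h,
                                    params.tip_rate_sd_um_h),
        is_primary=True, ramp_tau_h=params.primary_accel_tau_h,
    )
    tips: list[_Tip] = [_Tip(primary, spore, rng.uniform(0, 2 * math.pi))]
    branch_events: list[tuple[float, tuple[float, float]]] = []

    total_series = np.zeros(n)
    count_series = np.zeros(n, dtype=int)

    dt = params.sim_dt_h
    # per-substep angular noise scaled so that direction diffuses by
    # ~angle_noise_rad (std) per frame interval
    step_sigma = params.angle_noise_rad * math.sqrt(dt / params.frame_interval_h)

    # monolayer capacity: growth stalls once the chamber is packed;
    # the analysis truncates at 20 % coverage long before this cap
    cap = params.max_total_length_um
    if cap is None:
        cap = 0.5 * w * h / params.hypha_width_um

    # occupancy grid for tip avoidance (negative autotropism): cells store
    # the id of the first hypha that grew through them; a tip avoids any
    # destination whose 3x3 cell neighbourhood contains another hypha,
    # which enforces a raster-resolvable separation between centrelines
    grid_res = params.avoidance_grid_um
    occ = -np.ones((int(h / grid_res) + 6, int(w / grid_res) + 6), dtype=int)
    occ_len = np.zeros_like(occ, dtype=float)   # owner arc length at claim
    # chamber walls are themselves occupied space: the steering that keeps
    # hyphae apart also turns tips smoothly away from walls (no specular
    # corner kinks, no wall-hugging lanes)
    occ[:2, :] = -2
    occ[int(h / grid_res) + 3:, :] = -2
    occ[:, :2] = -2
    occ[:, int(w / grid_res) + 3:] = -2

    def cell(p: np.ndarray) -> tuple[int, int]:
        return (int(p[1] / grid_res) + 2, int(p[0] / grid_res) + 2)

    recent_um = 5.0

    def clear(p: np.ndarray, me: int, parent: int, my_len: float) -> bool:
        # a 3x3 cell neighbourhood must be free of other hyphae AND of the
        # tip's own older trail (only the recent ~2.5 um of own path is
        # allowed) — keeps centrelines raster-resolvable and prevents a
        # tip folding back onto itself
        ci, cj = cell(p)
        around = occ[ci - 1:ci + 2, cj - 1:cj + 2]
        around_len = occ_len[ci - 1:ci + 2, cj - 1:cj + 2]
        ok = (around == -1) | ((around == me)
                               & (my_len - around_len < recent_um))
        if parent >= 0:
            ok |= around == parent
        return bool(np.all(ok))

    # steering is curvature-capped: the turn per substep scales with the
    # arc laid down, so fast and slow tips trace equally smooth paths
    max_curvature = 2.0  # rad per um of arc
    lookahead = params.avoidance_lookahead_um

    frame_idx = int(np.searchsorted(times, t_g, side="left"))
    # frames strictly before germination are empty
    n_steps = max(0, int(math.ceil((horizon - t_g) / dt - 1e-9)))
    t = t_g
    total_len = 0.0
    for _ in range(n_steps):
        t1 = min(t + dt, horizon)
        for tip in tips:
            ds = tip.step_length(t, t1)
            if ds <= 0:
                continue
            if step_sigma > 0:
                tip.angle += rng.normal(0.0, step_sigma)
            if params.tip_avoidance:
                # monolayer volume exclusion: steer away from occupied
                # cells (looking one tube-width ahead); a fully surrounded
                # tip stalls until space opens.  Newborn branches may grow
                # through their parent's corridor while escaping it.
                me = tip.record.tip_id
                parent = tip.record.parent_id if (
                    tip.record.parent_id is not None
                    and tip.length < 4.0) else -1
                fallback = None
                turn = max_curvature * ds / 3.0
                deflections = (0.0, turn, -turn, 2 * turn, -2 * turn,
                               3 * turn, -3 * turn)
                for da in deflections:
                    cand = tip.angle + da
                    pts, out_angle, hit = _slide(tip.pos, cand, ds, w, h)
                    new = pts[-1]
                    if not clear(new, me, parent, tip.length):
                        continue
                    if fallback is None:
                        fallback = (pts, out_angle)
                    ua = np.array([math.cos(out_angle), math.sin(out_angle)])
                    probe = np.clip(new + lookahead * ua,
                                    [0.0, 0.0], [w, h])
                    if clear(probe, me, parent, tip.length):
                        fallback = (pts, out_angle)
                        break
                else:
                    if fallback is None:
                        continue  # stalled this substep
                pts, tip.angle = fallback
            else:
                pts, tip.angle, _ = _slide(tip.pos, tip.angle, ds, w, h)
            new = pts[-1]
            c = cell(new)
            if occ[c] == -1:
                occ[c] = tip.record.tip_id
                occ_len[c] = tip.length
            # realized arc: equals ds except when jammed at a wall/corner
            path_len = float(np.linalg.norm(pts[0] - tip.pos))
            if len(pts) > 1:
                path_len += float(np.linalg.norm(pts[1] - pts[0]))
            tip.pos = new
            tip.length += min(path_len, ds)
            if len(pts) > 1:
                # wall contact way-point, time split by path fraction
                frac = (np.linalg.norm(pts[0] - tip.verts[-1])
                        / max(ds, 1e-12))
                tip.times.append(t + frac * (t1 - t))
                tip.verts.append(pts[0].copy())
            tip.times.append(t1)
            tip.verts.append(new.copy())
        total_len = sum(tip.length for tip in tips)
        # branch whenever length per tip exceeds the HGU target; lateral
        # branches emerge where the monolayer leaves room (anchors whose
        # escape corridor is blocked are resampled)
        while total_len / len(tips) > params.target_hgu_um:
            spawned = False
            for _attempt in range(20):
                anchor_tip, anchor_pos, anchor_dir = _sample_anchor(tips, rng)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                angle = anchor_dir + sign * rng.uniform(math.pi / 3, math.pi / 2)
                if params.tip_avoidance:
                    u = np.array([math.cos(angle), math.sin(angle)])
                    probes = [np.clip(anchor_pos + s * u, [0, 0], [w, h])
                              for s in (0.8, 1.6)]
                    if not all(clear(pp, len(tips),
                                     anchor_tip.record.tip_id, 0.0)
                               for pp in probes):
                        continue
                rec = TipRecord(
                    tip_id=len(tips), parent_id=anchor_tip.record.tip_id,
                    birth_time_h=t1,
                    anchor_um=(float(anchor_pos[0]), float(anchor_pos[1])),
                    rate_um_h=_truncated_normal(rng, params.tip_rate_mean_um_h,
                                                params.tip_rate_sd_um_h),
                    is_primary=False,
                )
                tips.append(_Tip(rec, anchor_pos, angle))
                branch_events.append(
                    (t1, (float(anchor_pos[0]), float(anchor_pos[1]))))
                spawned = True
                break
            if not spawned:
                break  # no room anywhere this substep; retry on the next
        while frame_idx < n and times[frame_idx] <= t1 + 1e-9:
            total_series[frame_idx] = total_len
            count_series[frame_idx] = len(tips)
            frame_idx += 1
        t = t1
        if total_len >= cap:
            break
    # chamber packed (or horizon hit): remaining frames keep the last state
    if frame_idx < n:
        total_series[frame_idx:] = sum(tip.length for tip in tips)
        count_series[frame_idx:] = len(tips)

    geometry = _geometry_frames(tips, times)

    truth = GroundTruth(
        germinated=True, germination_time_h=t_g,
        tips=[tip.record for tip in tips], branch_events=branch_events,
        target_hgu_um=params.target_hgu_um, times_h=times,
        total_length_um=total_series, tip_count=count_series,
        implied_mu_h=params.tip_rate_mean_um_h / params.target_hgu_um,
    )
    return geometry, truth


def _sample_anchor(tips: list[_Tip], rng: np.random.Generator
                   ) -> tuple[_Tip, np.ndarray, float]:
    """Pick a point uniformly along the existing mycelium arc length."""
    lengths = np.array([tip.length for tip in tips])
    total = lengths.sum()
    u = rng.uniform(0, total)
    k = int(np.searchsorted(np.cumsum(lengths), u, side="right"))
    k = min(k, len(tips) - 1)
    tip = tips[k]
    s = u - (np.cumsum(lengths)[k] - lengths[k])
    verts = np.asarray(tip.verts)
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    j = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1))
    frac = 0.0 if seg[j] == 0 else (s - cum[j]) / seg[j]
    pos = verts[j] + frac * (verts[j + 1] - verts[j])
    d = verts[j + 1] - verts[j]
    direction = math.atan2(d[1], d[0]) if np.any(d) else rng.uniform(0, 2 * math.pi)
    return tip, pos, direction


def _geometry_frames(tips: list[_Tip], times: np.ndarray
                     ) -> list[list[np.ndarray]]:
    """Per-frame polylines (stable tip order, prefix property)."""
    frames: list[list[np.ndarray]] = []
    tip_times = [np.asarray(t.times) for t in tips]
    tip_verts = [np.asarray(t.verts) for t in tips]
    for t in times:
        polys: list[np.ndarray] = []
        for tt, vv in zip(tip_times, tip_verts):
            if t < tt[0] - 1e-12:
                continue
            m = int(np.searchsorted(tt, t + 1e-12, side="right"))
            if m >= len(tt):
                polys.append(vv)
            elif m >= 1:
                # interpolate the tip position at the frame time
                t0, t1 = tt[m - 1], tt[m]
                frac = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
                end = vv[m - 1] + frac * (vv[m] - vv[m - 1])
                polys.append(np.vstack([vv[:m], end]))
        frames.append(polys)
    return frames


def ground_truth_tracks(geometry: list[list[np.ndarray]],
                        timestamps_h: np.ndarray):
    """Per-tip arc-length trajectories sampled at the frame times.

    Builds one :class:`~hyphatrack.tracking.HyphaTrack` per simulated
    hypha directly from the generated polylines (geodesic length = true
    arc length from the birth anchor), bypassing rendering and
    segmentation — the reference against which image-based tracking and
    the tip-rate statistics are validated.
    """
    from .tracking import HyphaTrack, TrackSample

    n_tips = max((len(polys) for polys in geometry), default=0)
    tracks: list[HyphaTrack] = []
    for i in range(n_tips):
        track: HyphaTrack | None = None
        for k, polys in enumerate(geometry):
            # tips are ordered by birth: slot i exists once len(polys) > i
            if i >= len(polys):
                continue
            poly = polys[i]
            seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
            length = float(seg.sum())
            if track is None:
                track = HyphaTrack(track_id=i,
                                   anchor_pos=(float(poly[0][1]),
                                               float(poly[0][0])))
                tracks.append(track)
            track.samples.append(TrackSample(
                frame_index=k, timestamp_h=float(timestamps_h[k]),
                tip_pos=(float(poly[-1][1]), float(poly[-1][0])),
                geodesic_length_um=length))
    return tracks


# --------------------------------------------------------------------------
# rendering


def render_frames(geometry: list[list[np.ndarray]], params: SimulationParams,
                  *, polarity: str = "dark", blur_sigma_px: float = 1.0,
                  emit_clean_masks: bool = True, clean_only: bool = False,
                  max_coverage: float | None = None,
                  background: float = 200.0, foreground: float = 60.0,
                  stack_id: str = "synthetic") -> TimeLapseStack:
    """Rasterize per-frame polylines into a noisy grayscale stack.

    Hyphae are drawn at ``hypha_width_um``, dark on bright background by
    default (``polarity='bright'`` inverts).  Gaussian blur and additive
    Gaussian noise (``params.noise_sd``) model optics and camera noise.
    The noise-free binary raster is kept as ``clean_masks``.

    ``clean_only=True`` skips the intensity rendering (frames are the
    binary masks) — useful for segmentation-free validation runs.
    ``max_coverage`` stops rendering once the mask exceeds that chamber
    coverage fraction (the returned stack simply has fewer frames).
    """
    from skimage.draw import line as sk_line

    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    px = params.pixel_size_um
    shape = (
        int(round(params.chamber_height_um / px)),
        int(round(params.chamber_width_um / px)),
    )
    radius = max(1, int(params.hypha_width_um / (2 * px)))
    dr_off, dc_off = np.nonzero(_disk(radius))
    dr_off, dc_off = dr_off - radius, dc_off - radius
    rng = np.random.default_rng(params.seed + 880301)

    mask = np.zeros(shape, dtype=bool)     # running union (growth is monotone)
    drawn: dict[int, int] = {}             # tip slot -> vertices already drawn
    masks, frames = [], []
    for polys in geometry:
        new_r, new_c = [], []
        for i, poly in enumerate(polys):
            start = max(drawn.get(i, 1) - 1, 0)
            pts = np.clip(
                np.round(poly[:, ::-1] / px).astype(int),  # (y, x) -> (row, col)
                0, [shape[0] - 1, shape[1] - 1],
            )
            for j in range(start, len(pts) - 1):
                rr, cc = sk_line(pts[j, 0], pts[j, 1], pts[j + 1, 0], pts[j + 1, 1])
                new_r.append(rr)
                new_c.append(cc)
            if len(pts) == 1:
                new_r.append(pts[:1, 0])
                new_c.append(pts[:1, 1])
            drawn[i] = max(drawn.get(i, 0), len(poly) - 1)
        if new_r:
            rr = np.concatenate(new_r)
            cc = np.concatenate(new_c)
            # stamp the hypha-width disk around every new centreline pixel
            for dr, dc in zip(dr_off, dc_off):
                r2, c2 = rr + dr, cc + dc
                ok = (r2 >= 0) & (r2 < shape[0]) & (c2 >= 0) & (c2 < shape[1])
                mask[r2[ok], c2[ok]] = True
        masks.append(mask.copy())
        if clean_only:
            frames.append(mask)
        else:
            img = np.full(shape, background)
            img[mask] = foreground
            if polarity == "bright":
                img = background + foreground - img
            if blur_sigma_px > 0:
                img = ndimage.gaussian_filter(img, blur_sigma_px)
            if params.noise_sd > 0:
                img = img + rng.normal(0.0, params.noise_sd, shape)
            frames.append(img)
        if max_coverage is not None and mask.sum() > max_coverage * mask.size:
            break

    frames_arr = (np.asarray(frames, dtype=bool) if clean_only
                  else np.asarray(frames, dtype=float))
    stack = TimeLapseStack(
        frames=frames_arr, timestamps_h=params.timestamps_h[: len(frames)],
        pixel_size_um=px, stack_id=stack_id,
        clean_masks=np.asarray(masks) if emit_clean_masks else None,
    )
    if px > params.hypha_width_um:
        stack.qc_flags.append("pixel_size_coarser_than_hypha_width")
    return stack


def _disk(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return (x * x + y * y) <= radius * radius


# --------------------------------------------------------------------------
# bare curves and plate signals


def simulate_length_curve(mu_h: float, L0_um: float, noise_cv: float,
                          times: np.ndarray,
                          seed: int | None = None) -> np.ndarray:
    """Exponential total-length curve with multiplicative lognormal noise.

    ``L(t) = L0 * exp(mu * t) * eps_t`` with ``ln eps_t ~ N(0, noise_cv)``;
    deterministic when ``noise_cv == 0``.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if mu_h <= 0 or L0_um <= 0 or noise_cv < 0:
        raise ValueError("require mu_h > 0, L0_um > 0, noise_cv >= 0")
    curve = L0_um * np.exp(mu_h * times)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        curve = curve * np.exp(rng.normal(0.0, noise_cv, times.shape))
    return curve


@dataclass
class ScatterSignalParams:
    """Shape of a synthetic scattered-light (biomass proxy) signal."""

    lag_h: float = 9.3
    mu_h: float = 0.33
    amplitude: float = 15.0
    blank_level: float = 100.0
    saturation_level: float = 600.0
    noise_sd: float = 0.5
    sample_interval_h: float = 1.0 / 6.0   # BioLector-style 10 min interval
    duration_h: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.mu_h <= 0 or self.amplitude <= 0 or self.saturation_level <= 0:
            raise ValueError("mu_h, amplitude, saturation_level must be positive")
        if self.sample_interval_h <= 0 or self.duration_h <= 0:
            raise ValueError("sampling parameters must be positive")


def simulate_scatter_signal(params: ScatterSignalParams, well_id: str = "A01"):
    """Lag + exponential + logistic saturation, plus Gaussian noise.

    Above the blank the noise-free signal is ``M*E/(M+E)`` with
    ``E = amplitude * exp(mu*(t - lag))`` and ``M = saturation - blank``:
    exponential with rate ``mu`` while ``E << M``, capped at the
    saturation level.
    """
    from .mtpc import ScatterSignal

    params.validate()
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_h + 1e-9, params.sample_interval_h)
    m = params.saturation_level - params.blank_level
    growth = np.zeros_like(t)
    after = t >= params.lag_h
    e = params.amplitude * np.exp(params.mu_h * (t[after] - params.lag_h))
    growth[after] = m * e / (m + e)
    values = params.blank_level + growth
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, t.shape)
    return ScatterSignal(well_id=well_id, timestamps_h=t, intensity=values)
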