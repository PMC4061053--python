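"""Synthetic 4-D BOLD data with known attentional ground truth.

Every voxel's neural drive (in percent of baseline intensity) is a linear
combination of condition indicators derived from the block design, from the
point of view of the cylinder contralateral to the voxel's hemisphere:

    s(t) = r * [ g_stim * S(t) + g_att * S(t) A(t) + g_feat * S(t) U(t) Same(t) ]
           + w_dir * D(t) S(t)

where S marks volumes in which the contralateral cylinder is present (active
trials; the passive static-dots baseline has S = 0), A marks volumes in
which it is attended, U = S - A marks it unattended, Same marks trials on
which attended and unattended cylinders rotate in the same direction, and
D in {+1, -1} is the contralateral cylinder's rotation direction
(counter-clockwise positive).  ``g_feat`` is the feature-similarity
("global feature attention") gain: the same-direction boost of the response
to the *unattended* cylinder, on the order of 0.05% BOLD.

``r`` stands for per-voxel sensitivity factors (lognormal, population mean
1) drawn *independently* for the stimulus, attention and feature terms, and
``w_dir`` is a zero-mean per-voxel direction preference.  Together they
create the spatially heterogeneous, ROI-mean-free structure that
multivariate decoding feeds on — voxels differ in their modulation ratios,
which survives z-scoring — while leaving the ROI-average (univariate)
expectations equal to the population gains.  The drive is convolved with a
gamma hemodynamic
response function (mean delay 6 s, SD 3 s), scaled onto a baseline
intensity, and corrupted with per-voxel linear drift and AR(1) Gaussian
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .design import Design, design_to_events

__all__ = [
    "ROI_NAMES",
    "RoiSpec",
    "SimulationParams",
    "BoldDataset",
    "make_rois",
    "contralateral_side",
    "hrf_kernel",
    "neural_drive",
    "neural_signal",
    "simulate_dataset",
    "simulate_eye_traces",
]

ROI_NAMES = ("V1", "V2", "V3", "hV4", "V3a/b", "V7", "hMT+")
HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class RoiSpec:
    """One region of interest: a labelled set of voxels in one hemisphere."""

    name: str
    hemisphere: str
    label: int                 # value in the integer label volume
    indices: tuple             # flat voxel indices into the grid

    @property
    def n_voxels(self) -> int:
        return len(self.indices)


def contralateral_side(hemisphere: str) -> str:
    """Visual-field side a hemisphere responds to (contralateral mapping)."""
    return {"left": "right", "right": "left"}[hemisphere]


def make_rois(shape: tuple[int, int, int] = (20, 20, 10),
              names: tuple[str, ...] = ROI_NAMES) -> tuple[np.ndarray, list[RoiSpec]]:
    """Carve a voxel grid into disjoint left/right-hemisphere ROI slabs.

    The x axis is split into hemispheres and the y axis into one strip per
    area, so ``len(names)`` areas x 2 hemispheres fit in the grid.  Returns
    the integer label volume (0 = background) and the ROI specs.
    """
    nx, ny, nz = shape
    strip = ny // len(names)
    if strip < 1 or nx < 2:
        raise ValueError("grid too small for the requested ROIs")
    labels = np.zeros(shape, dtype=np.int16)
    specs = []
    lab = 1
    for i, name in enumerate(names):
        for hemi in HEMISPHERES:
            xs = slice(0, nx // 2) if hemi == "left" else slice(nx // 2, nx)
            mask = np.zeros(shape, dtype=bool)
            mask[xs, i * strip:(i + 1) * strip, :] = True
            labels[mask] = lab
            specs.append(RoiSpec(name=name, hemisphere=hemi, label=lab,
                                 indices=tuple(np.flatnonzero(mask.ravel()))))
            lab += 1
    return labels, specs


@dataclass(frozen=True)
class SimulationParams:
    """Population-level generative parameters.  Gains are in % of baseline."""

    baseline: float = 100.0       # raw image intensity
    g_stim: float = 1.0           # stimulus-driven response, %BOLD
    g_att: float = 0.5            # spatial-attention gain, %BOLD
    g_feat: float = 0.05          # feature-similarity gain, %BOLD
    w_dir_sd: float = 0.2         # SD of per-voxel direction preference, %BOLD
    gain_dispersion: float = 0.3  # SD of log responsiveness across voxels
    noise_sd: float = 0.5         # stationary AR(1) noise SD, % of baseline
    ar1: float = 0.3              # AR(1) coefficient
    drift_pct: float = 0.5        # SD of per-voxel linear drift over a scan, %
    hrf_delay: float = 6.0        # seconds
    hrf_sd: float = 3.0           # seconds

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not abs(self.ar1) < 1:
            raise ValueError("|ar1| must be < 1")


def hrf_kernel(delay: float = 6.0, sd: float = 3.0, dt: float = 4.0) -> np.ndarray:
    """Gamma hemodynamic response kernel with given mean delay and SD.

    Moment matching gives shape ``(delay/sd)**2`` and scale ``sd**2/delay``
    (shape 4, scale 1.5 for the defaults).  The kernel integrates the gamma
    density over bins of width ``dt`` and is normalized to unit sum, so
    convolving a sustained unit drive yields a unit plateau.
    """
    if delay <= 0 or sd <= 0 or dt <= 0:
        raise ValueError("delay, sd and dt must be positive")
    shape = (delay / sd) ** 2
    scale = sd * sd / delay
    support = delay + 8.0 * sd
    n = int(np.ceil(support / dt))
    edges = np.arange(n + 1) * dt
    k = np.diff(stats.gamma.cdf(edges, a=shape, scale=scale))
    return k / k.sum()


def neural_drive(events: pd.DataFrame, scan: int, side: str,
                 n_volumes: int) -> np.ndarray:
    """Condition indicator matrix for one scan and one cylinder side.

    Columns: ``S`` (cylinder present), ``S*A`` (present and attended),
    ``S*U*Same`` (present, unattended, rotating like the attended one) and
    ``S*D`` (present, signed rotation direction).  One volume per 4-s trial.
    """
    X = np.zeros((n_volumes, 4))
    ev = events[events["scan"] == scan]
    if ev.empty:
        raise ValueError(f"no events for scan {scan}")
    for row in ev.itertuples():
        if row.condition.startswith("passive"):
            continue
        v = int(row.volume)
        attended = row.cue_side == side
        direction = (row.attended_direction if attended
                     else row.unattended_direction)
        if direction is None or (isinstance(direction, float) and np.isnan(direction)):
            raise ValueError("active event lacks a rotation-direction label")
        X[v, 0] = 1.0
        if attended:
            X[v, 1] = 1.0
        elif row.similarity == "same":
            X[v, 2] = 1.0
        X[v, 3] = 1.0 if direction == "counterclockwise" else -1.0
    return X


def neural_signal(events: pd.DataFrame, scan: int, roi: RoiSpec,
                  gains: tuple[float, float, float, float],
                  n_volumes: int) -> np.ndarray:
    """Pre-hemodynamic neural time course (in %) for one voxel in ``roi``.

    ``gains = (g_stim, g_att, g_feat, w_dir)``.  Passive baseline volumes
    are exactly zero.
    """
    X = neural_drive(events, scan, contralateral_side(roi.hemisphere), n_volumes)
    return X @ np.asarray(gains, dtype=float)


@dataclass
class BoldDataset:
    """A simulated 4-D dataset plus everything needed to analyze it."""

    data: np.ndarray            # (x, y, z, t) intensities
    tr: float
    roi_labels: np.ndarray      # (x, y, z) integer labels, 0 = background
    rois: list[RoiSpec]
    events: pd.DataFrame
    n_scans: int
    volumes_per_scan: int
    ground_truth: dict

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def roi_mask(self, name: str, hemisphere: str) -> np.ndarray:
        for roi in self.rois:
            if roi.name == name and roi.hemisphere == hemisphere:
                return self.roi_labels == roi.label
        raise KeyError(f"no ROI {name!r} in {hemisphere!r} hemisphere")

    def scan_slice(self, scan: int) -> slice:
        return slice(scan * self.volumes_per_scan,
                     (scan + 1) * self.volumes_per_scan)

    def save(self, directory) -> None:
        """Write NIfTI volumes (TR in the header), events TSV and truth JSON."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        img = nib.Nifti1Image(self.data.astype(np.float32), np.eye(4))
        img.header.set_zooms((1.0, 1.0, 1.0, self.tr))
        nib.save(img, directory / "bold.nii.gz")
        nib.save(nib.Nifti1Image(self.roi_labels.astype(np.int16), np.eye(4)),
                 directory / "roi_labels.nii.gz")
        self.events.to_csv(directory / "events.tsv", sep="\t", index=False)
        truth = {k: v for k, v in self.ground_truth.items()
                 if not isinstance(v, np.ndarray)}
        truth["rois"] = [{"name": r.name, "hemisphere": r.hemisphere,
                          "label": int(r.label), "n_voxels": r.n_voxels}
                         for r in self.rois]
        truth["n_scans"] = self.n_scans
        truth["volumes_per_scan"] = self.volumes_per_scan
        (directory / "ground_truth.json").write_text(json.dumps(truth, indent=2))

    @classmethod
    def load(cls, directory) -> "BoldDataset":
        import nibabel as nib

        directory = Path(directory)
        img = nib.load(directory / "bold.nii.gz")
        data = np.asarray(img.dataobj, dtype=np.float32)
        tr = float(img.header.get_zooms()[3])
        labels = np.asarray(nib.load(directory / "roi_labels.nii.gz").dataobj,
                            dtype=np.int16)
        events = pd.read_csv(directory / "events.tsv", sep="\t")
        truth = json.loads((directory / "ground_truth.json").read_text())
        rois = [RoiSpec(name=r["name"], hemisphere=r["hemisphere"],
                        label=r["label"],
                        indices=tuple(np.flatnonzero((labels == r["label"]).ravel())))
                for r in truth.pop("rois")]
        n_scans = truth.pop("n_scans")
        vps = truth.pop("volumes_per_scan")
        return cls(data=data, tr=tr, roi_labels=labels, rois=rois,
                   events=events, n_scans=n_scans, volumes_per_scan=vps,
                   ground_truth=truth)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               sd: float, ar1: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with stationary SD ``sd``."""
    if sd == 0:
        return np.zeros(shape)
    innov_sd = sd * np.sqrt(1.0 - ar1 ** 2)
    w = rng.normal(0.0, innov_sd, size=shape)
    out = signal.lfilter([1.0], [1.0, -ar1], w, axis=-1)
    # start from a stationary draw instead of zero
    out[..., 0] = rng.normal(0.0, sd, size=shape[:-1])
    for t in range(1, min(8, shape[-1])):
        out[..., t] = ar1 * out[..., t - 1] + w[..., t]
    return out


def simulate_dataset(design: Design | pd.DataFrame,
                     rois: tuple[np.ndarray, list[RoiSpec]] | None = None,
                     params: SimulationParams | None = None,
                     seed: int = 0,
                     shape: tuple[int, int, int] = (20, 20, 10),
                     volumes_per_scan: int | None = None) -> BoldDataset:
    """Generate a reproducible 4-D dataset from a block design.

    intensity = baseline * (1 + (hrf (x) s)(t)/100 + drift(t)/100) + AR(1) noise.
    Per-voxel responsiveness ``r`` is lognormal with population mean 1 and
    per-voxel direction weight ``w_dir`` is N(0, w_dir_sd); both are stored
    in ``ground_truth`` together with the population parameters.
    """
    params = params or SimulationParams()
    if isinstance(design, Design):
        events = design_to_events(design)
        tr = design.params.tr
        n_scans = design.n_scans
        vps = design.volumes_per_scan
    else:
        events = design
        tr = float(events.get("tr", pd.Series([4.0])).iloc[0])
        n_scans = int(events["scan"].max()) + 1
        if volumes_per_scan is None:
            raise ValueError("volumes_per_scan required with a raw event table")
        vps = volumes_per_scan
    if rois is None:
        rois = make_rois(shape)
    labels, specs = rois
    shape = labels.shape
    n_vox = int(np.prod(shape))
    T = n_scans * vps

    rng = np.random.default_rng(seed)

    def _lognormal_mean_one() -> np.ndarray:
        r = np.exp(rng.normal(0.0, params.gain_dispersion, size=n_vox))
        return r / np.exp(params.gain_dispersion ** 2 / 2.0)

    # independent per-voxel sensitivity for each gain component: voxels
    # differ in their stimulus drive, attentional modulation and
    # feature-similarity modulation (distinct neural subpopulations), so
    # modulation *ratios* vary across voxels — the pattern structure that
    # survives z-scoring and ROI-mean removal
    r_stim = _lognormal_mean_one()
    r_att = _lognormal_mean_one()
    r_feat = _lognormal_mean_one()
    w_map = rng.normal(0.0, params.w_dir_sd, size=n_vox)

    pct = np.zeros((n_vox, T))
    kernel = hrf_kernel(params.hrf_delay, params.hrf_sd, dt=tr)
    for scan in range(n_scans):
        ts = slice(scan * vps, (scan + 1) * vps)
        drives = {}
        for side in ("left", "right"):
            X = neural_drive(events, scan, side, vps)
            C = np.empty_like(X)
            for j in range(X.shape[1]):
                C[:, j] = np.convolve(X[:, j], kernel)[:vps]
            drives[side] = C
        for roi in specs:
            idx = np.asarray(roi.indices)
            C = drives[contralateral_side(roi.hemisphere)]
            amps = np.column_stack([
                params.g_stim * r_stim[idx],
                params.g_att * r_att[idx],
                params.g_feat * r_feat[idx],
                w_map[idx],
            ])
            pct[idx, ts] += (C @ amps.T).T
        # per-voxel linear drift, independent across scans
        slope = rng.normal(0.0, params.drift_pct, size=n_vox)
        ramp = np.linspace(-0.5, 0.5, vps)
        pct[:, ts] += slope[:, None] * ramp[None, :]

    noise = _ar1_noise(rng, (n_vox, T), params.baseline * params.noise_sd / 100.0,
                       params.ar1)
    data = params.baseline * (1.0 + pct / 100.0) + noise
    truth = {
        "params": asdict(params),
        "seed": int(seed),
        "responsiveness": r_stim,
        "att_responsiveness": r_att,
        "feat_responsiveness": r_feat,
        "direction_weights": w_map,
    }
    return BoldDataset(
        data=data.reshape(*shape, T),
        tr=tr, roi_labels=labels, rois=specs, events=events,
        n_scans=n_scans, volumes_per_scan=vps, ground_truth=truth,
    )


def simulate_eye_traces(events: pd.DataFrame,
                        rate: float = 500.0,
                        duration: float = 4.0,
                        jitter_sd: float = 0.2,
                        tau: float = 0.5,
                        attend_offset: float = 0.0,
                        seed: int = 0) -> tuple[np.ndarray, pd.DataFrame]:
    """Trial-wise fixation traces as an Ornstein-Uhlenbeck jitter process.

    Returns ``(traces, labels)`` where ``traces`` has shape
    ``(n_trials, n_samples, 2)`` (x then y, degrees) and ``labels`` carries
    one row per trial with a ``condition_group`` in {baseline, attend_left,
    attend_right}.  ``jitter_sd`` is the stationary fixation-jitter SD and
    ``tau`` its correlation time in seconds.  A nonzero ``attend_offset``
    shifts horizontal position toward the cued side on active trials (a
    fixation-failure scenario; the default models stable fixation).
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * rate))
    rho = float(np.exp(-1.0 / (tau * rate)))
    n_trials = len(events)
    innov = rng.normal(0.0, jitter_sd * np.sqrt(1.0 - rho ** 2),
                       size=(n_trials, n_samples, 2))
    traces = signal.lfilter([1.0], [1.0, -rho], innov, axis=1)
    traces[:, 0, :] = rng.normal(0.0, jitter_sd, size=(n_trials, 2))

    passive = events["condition"].str.startswith("passive").to_numpy()
    group = np.where(passive, "baseline",
                     np.where(events["cue_side"].to_numpy() == "left",
                              "attend_left", "attend_right"))
    if attend_offset != 0.0:
        off = np.where(group == "attend_right", attend_offset,
                       np.where(group == "attend_left", -attend_offset, 0.0))
        traces[:, :, 0] += off[:, None]
    labels = pd.DataFrame({
        "trial": np.arange(n_trials),
        "condition_group": group,
        "condition": events["condition"].to_numpy(),
        "similarity": events["similarity"].to_numpy(),
        "attended_direction": events["attended_direction"].to_numpy(),
    })
    return traces, labels
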