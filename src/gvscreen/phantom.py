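"""Synthetic ultrasound scans of GV-expressing samples in well phantoms.

Gas vesicles respond to insonation in three pressure regimes: linear
scattering at low pressure, nonlinear scattering above a buckling threshold
(shell deformation generates harmonics that stand out against tissue), and
irreversible collapse above a collapse threshold, which erases the signal.
The simulator renders only the nonlinear-signal channel, which is what the
screening pipeline quantifies:

* below the buckling threshold a well contributes nothing;
* above it, the nonlinear signal plateaus at a per-well amplitude ``A``,
  attenuated by a logistic survival term
  ``S(q) = 1 / (1 + exp((q - p_col) / w_col))`` of the *running maximum*
  pressure ``q`` the well has experienced — collapse is irreversible, so
  signal never recovers after a high-pressure pulse.

Pixels are Rayleigh-distributed speckle (the classical envelope statistics
of ultrasound) with per-pixel mean = background ``B`` plus the well's
response; noiseless mode replaces the draw by the mean for exact tests.

Three scan protocols mirror the acquisition modes of an acoustic plate
reader: a pre/post-collapse pair at one voltage (the difference isolates
GV-specific signal), a voltage ramp (pre/post pairs across voltages, each
pair acquired at the same voltage), and a collapse ramp (ascending voltages,
imaged at each step, from which collapse pressure curves are fit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .grid import WellGrid, well_name

PRECOLLAPSE = "precollapse"
POSTCOLLAPSE = "postcollapse"
COLLAPSE_PULSE = "collapse-pulse"
PHASES = (PRECOLLAPSE, COLLAPSE_PULSE, POSTCOLLAPSE)

PRE_POST = "pre_post"
VOLTAGE_RAMP = "voltage_ramp"
COLLAPSE_RAMP = "collapse_ramp"
SCAN_TYPES = (PRE_POST, VOLTAGE_RAMP, COLLAPSE_RAMP)

#: default linear voltage->pressure calibration, kPa per volt
DEFAULT_KPA_PER_VOLT = 50.0

# exp() arguments below this are flushed; far past the midpoint the survival
# term overflows the exponential and underflows to exact floating-point zero
_EXP_CLAMP = 700.0


def pressure_from_voltage(
    voltage: float, kpa_per_volt: float = DEFAULT_KPA_PER_VOLT
) -> float:
    """Linear transducer calibration: peak pressure = coeff x voltage."""
    if voltage < 0:
        raise ValueError(f"negative voltage {voltage}")
    if kpa_per_volt <= 0:
        raise ValueError("kpa_per_volt must be positive")
    return kpa_per_volt * voltage


@dataclass(frozen=True)
class WellResponse:
    """Acoustic parameters of one well's sample.

    amplitude
        mean nonlinear signal above buckling (arbitrary intensity units);
        0 for empty wells.
    p_buck, p_col, w_col
        buckling threshold, collapse midpoint, and collapse transition
        width, all in kPa.
    """

    amplitude: float
    p_buck: float = 150.0
    p_col: float = 300.0
    w_col: float = 20.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 < self.p_buck < self.p_col:
            raise ValueError("need 0 < p_buck < p_col")
        if self.w_col <= 0:
            raise ValueError("w_col must be positive")


EMPTY_WELL = WellResponse(amplitude=0.0)


class CollapseState:
    """Per-well maximum pressure experienced so far (kPa); non-decreasing."""

    def __init__(self, grid: WellGrid):
        self.grid = grid
        self.max_pressure = np.zeros((grid.n_rows, grid.n_cols))

    def exposed(self, pressure: float) -> None:
        if pressure < 0:
            raise ValueError("pressure must be >= 0")
        np.maximum(self.max_pressure, pressure, out=self.max_pressure)

    def copy(self) -> "CollapseState":
        out = CollapseState(self.grid)
        out.max_pressure = self.max_pressure.copy()
        return out


def survival(q: float | np.ndarray, p_col: float, w_col: float):
    """Fraction of GVs surviving a maximum experienced pressure ``q``."""
    z = np.maximum((np.asarray(q, dtype=float) - p_col) / w_col, -_EXP_CLAMP)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(z))


def nonlinear_response(
    well: WellResponse, pressure: float, state_pressure: float = 0.0
) -> float:
    """Mean nonlinear intensity of a well at ``pressure`` given the maximum
    pressure ``state_pressure`` it has already experienced.

    Zero below the buckling threshold; otherwise the amplitude plateau
    scaled by the survival of the running-maximum pressure (including the
    current exposure).
    """
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    if pressure < well.p_buck:
        return 0.0
    q = max(pressure, state_pressure)
    return float(well.amplitude * survival(q, well.p_col, well.w_col))


@dataclass(frozen=True)
class NoiseModel:
    """Rayleigh speckle parameterized by its mean; ``speckle=False`` renders
    exact per-pixel means for closed-form tests."""

    background_mean: float = 2.0
    speckle: bool = True

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")

    def sample(self, mean_image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.speckle:
            return mean_image.copy()
        # Rayleigh mean = scale * sqrt(pi/2)
        scale = mean_image * np.sqrt(2.0 / np.pi)
        return rng.rayleigh(scale=scale)


@dataclass(frozen=True)
class FrameSpec:
    voltage: float
    phase: str
    scan_type: str

    def __post_init__(self) -> None:
        if self.voltage < 0:
            raise ValueError("voltage must be >= 0")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"unknown scan type {self.scan_type!r}")


@dataclass(frozen=True)
class ScanProtocol:
    """An ordered frame sequence of one scan type.

    For pre/post and voltage-ramp protocols every precollapse frame must
    have a postcollapse partner at the same voltage — the two images entering
    a difference-SBR calculation are always acquired at the same voltage.
    """

    frames: tuple[FrameSpec, ...]
    scan_type: str

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("protocol has no frames")
        if self.scan_type not in SCAN_TYPES:
            raise ValueError(f"unknown scan type {self.scan_type!r}")
        for f in self.frames:
            if f.scan_type != self.scan_type:
                raise ValueError("frame scan_type differs from protocol scan_type")
        if self.scan_type in (PRE_POST, VOLTAGE_RAMP):
            pre = sorted(f.voltage for f in self.frames if f.phase == PRECOLLAPSE)
            post = sorted(f.voltage for f in self.frames if f.phase == POSTCOLLAPSE)
            if pre != post:
                raise ValueError(
                    f"unpaired pre/post voltages: pre={pre}, post={post}"
                )


def pre_post_protocol(
    imaging_voltage: float = 4.4, collapse_voltage: float = 30.0
) -> ScanProtocol:
    """One precollapse image, a collapse pulse, one postcollapse image."""
    return ScanProtocol(
        frames=(
            FrameSpec(imaging_voltage, PRECOLLAPSE, PRE_POST),
            FrameSpec(collapse_voltage, COLLAPSE_PULSE, PRE_POST),
            FrameSpec(imaging_voltage, POSTCOLLAPSE, PRE_POST),
        ),
        scan_type=PRE_POST,
    )


def voltage_ramp_protocol(
    voltages: Sequence[float], collapse_voltage: float = 30.0
) -> ScanProtocol:
    """Precollapse images across ``voltages``, a collapse pulse, then the
    matching postcollapse images at the same voltages."""
    vs = tuple(voltages)
    if not vs:
        raise ValueError("voltage ramp needs at least one voltage")
    frames = (
        tuple(FrameSpec(v, PRECOLLAPSE, VOLTAGE_RAMP) for v in vs)
        + (FrameSpec(collapse_voltage, COLLAPSE_PULSE, VOLTAGE_RAMP),)
        + tuple(FrameSpec(v, POSTCOLLAPSE, VOLTAGE_RAMP) for v in vs)
    )
    return ScanProtocol(frames=frames, scan_type=VOLTAGE_RAMP)


def collapse_ramp_protocol(voltages: Sequence[float]) -> ScanProtocol:
    """Image at each of an ascending series of voltages; GVs progressively
    collapse as the ramp exceeds their collapse pressure."""
    vs = tuple(voltages)
    if list(vs) != sorted(vs) or len(set(vs)) != len(vs):
        raise ValueError("collapse ramp voltages must be strictly increasing")
    frames = tuple(FrameSpec(v, PRECOLLAPSE, COLLAPSE_RAMP) for v in vs)
    return ScanProtocol(frames=frames, scan_type=COLLAPSE_RAMP)


@dataclass
class ScanStack:
    """Rendered frames plus per-frame metadata for one scan."""

    frames: np.ndarray  # (n_frames, H, W)
    meta: pd.DataFrame  # columns: frame_index, voltage, phase, scan_type

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if len(self.meta) != self.frames.shape[0]:
            raise ValueError("metadata length != frame count")

    @property
    def scan_type(self) -> str:
        return str(self.meta["scan_type"].iloc[0])

    def save(self, tiff_path, meta_path) -> None:
        tifffile.imwrite(tiff_path, self.frames.astype(np.float32))
        self.meta.to_csv(meta_path, index=False)

    @classmethod
    def load(cls, tiff_path, meta_path) -> "ScanStack":
        frames = np.asarray(tifffile.imread(tiff_path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        meta = pd.read_csv(meta_path)
        return cls(frames=frames, meta=meta)


def _well_map_to_array(
    grid: WellGrid, wells: Mapping[str, WellResponse]
) -> list[tuple[int, int, WellResponse]]:
    known = set(grid.well_names())
    unknown = sorted(set(wells) - known)
    if unknown:
        raise ValueError(f"wells outside the grid: {unknown}")
    out = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            out.append((r, c, wells.get(well_name(r, c), EMPTY_WELL)))
    return out


def render_frame(
    grid: WellGrid,
    wells: Mapping[str, WellResponse],
    pressure: float,
    state: CollapseState,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render one nonlinear-signal frame and record the exposure in
    ``state`` (element-wise running maximum).

    Sample-ROI pixels have mean ``B + nonlinear_response``; everything else
    has mean ``B``.  With speckle enabled the pixel values are Rayleigh
    draws at those means.
    """
    mean_image = np.full(grid.image_shape, noise.background_mean, dtype=float)
    for r, c, well in _well_map_to_array(grid, wells):
        resp = nonlinear_response(well, pressure, state.max_pressure[r, c])
        if resp:
            ys, xs, mask = grid.disk_mask(grid.well_center(r, c), grid.roi_radius)
            block = mean_image[ys, xs]
            block[mask] += resp
            mean_image[ys, xs] = block
    state.exposed(pressure)
    return noise.sample(mean_image, rng)


def run_protocol(
    protocol: ScanProtocol,
    grid: WellGrid,
    wells: Mapping[str, WellResponse],
    noise: NoiseModel,
    seed: int,
    kpa_per_volt: float = DEFAULT_KPA_PER_VOLT,
    state: CollapseState | None = None,
) -> ScanStack:
    """Run a scan protocol, rendering frames in order with a persistent
    collapse state.  Collapse-pulse frames update the state but emit no
    image.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    state = state if state is not None else CollapseState(grid)
    frames: list[np.ndarray] = []
    rows: list[dict] = []
    for spec in protocol.frames:
        pressure = pressure_from_voltage(spec.voltage, kpa_per_volt)
        if spec.phase == COLLAPSE_PULSE:
            state.exposed(pressure)
            continue
        image = render_frame(grid, wells, pressure, state, noise, rng)
        rows.append(
            {
                "frame_index": len(frames),
                "voltage": spec.voltage,
                "phase": spec.phase,
                "scan_type": spec.scan_type,
            }
        )
        frames.append(image)
    return ScanStack(frames=np.stack(frames), meta=pd.DataFrame(rows))


def wells_from_assignments(
    assignments: pd.DataFrame,
    amplitudes: Mapping[str, float],
    well_params: WellResponse = WellResponse(amplitude=1.0),
) -> dict[str, WellResponse]:
    """Build a well->response map from a plate-map table.

    ``assignments`` needs columns ``well``, ``sample_id`` and ``role``;
    amplitudes are looked up per sample_id (empty wells get amplitude 0).
    Collapse parameters are shared from ``well_params``.
    """
    out: dict[str, WellResponse] = {}
    for row in assignments.itertuples(index=False):
        if getattr(row, "role", "mutant") == "empty":
            out[row.well] = EMPTY_WELL
            continue
        try:
            amp = amplitudes[row.sample_id]
        except KeyError:
            raise KeyError(f"no amplitude for sample {row.sample_id!r}") from None
        out[row.well] = replace(well_params, amplitude=float(amp))
    return out


def titration_amplitudes(
    glucose_levels: Sequence[float],
    arabinose_levels: Sequence[float],
    peak: tuple[float, float] = (0.25, 0.05),
    peak_amplitude: float = 10.0,
    width_cells: float = 1.5,
) -> dict[tuple[float, float], float]:
    """Ground-truth expression surface for autoinduction titrations.

    Expression responds to the induction point's position on the titration
    grid; the surface is a Gaussian bump in grid-index space centered on the
    ``peak`` (glucose, arabinose) cell.  Index space is used because
    arabinose levels span decades (including zero), so distances in
    concentration units would be meaningless.
    """
    gi = {g: i for i, g in enumerate(glucose_levels)}
    ai = {a: j for j, a in enumerate(arabinose_levels)}
    if peak[0] not in gi or peak[1] not in ai:
        raise ValueError(f"peak {peak} is not a grid cell")
    out = {}
    for g in glucose_levels:
        for a in arabinose_levels:
            d2 = (gi[g] - gi[peak[0]]) ** 2 + (ai[a] - ai[peak[1]]) ** 2
            out[(g, a)] = peak_amplitude * float(np.exp(-d2 / (2 * width_cells**2)))
    return out
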