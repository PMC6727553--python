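"""Seedable synthetic rat polysomnography with known ground truth.

Generates EEG (200 Hz) + EMG (500 Hz) recordings whose per-stage spectral
content follows the five stage signatures used by the scorer:

* wake — low-amplitude theta over a broadband (movement/high-frequency)
  background, with large EMG;
* NREM1 — delta activity over less than half the epoch plus sleep
  spindles, reduced EMG;
* NREM2 — delta activity occupying more than half the epoch, low EMG;
* TS — regular theta intermixed with short high-amplitude spindles, low
  EMG;
* REM — regular theta on a slightly elevated (desynchronized) background,
  near-absent EMG.

Rhythmic activity is synthesized as a random-phase harmonic series on the
0.5-Hz grid of the 2-s analysis segments (independent Gaussian quadrature
amplitudes per harmonic, rescaled to a target rms).  This fills the band
like real slow-wave/theta activity while staying spectrally compact: a
component off the grid, or a filtered-noise band, smears substantial
power into neighboring bands through the rectangular-window periodogram
and corrupts the very signatures the recipes encode.  Activity duty
cycles and spindle bursts are segment-aligned (2 s) for the same reason.
Stage sequences come from a per-epoch Markov chain with a physiological
wiring (W↔NREM1↔NREM2→TS→REM→W).  Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .io import STAGES_5, Hypnogram, Recording


class BandActivity(NamedTuple):
    """Band-limited harmonic activity: [lo_hz, hi_hz) at 0.5-Hz resolution,
    target rms (µV), duty = fraction of the epoch it covers (contiguous
    from epoch start, rounded to whole 2-s segments)."""

    lo_hz: float
    hi_hz: float
    rms: float
    duty: float = 1.0


class SpindleActivity(NamedTuple):
    """Spindle bursts: one full 2-s segment each (within the 1-3-s range
    reported for rat spindles), in ``n_segments`` distinct random segments."""

    lo_hz: float
    hi_hz: float
    rms: float
    n_segments: int


@dataclass
class StageRecipe:
    """Synthesis parameters for one stage's 10-s epochs."""

    activities: tuple[BandActivity, ...] = ()
    spindles: Optional[SpindleActivity] = None
    noise_sd: float = 5.0     # broadband EEG background, µV
    emg_sd: float = 10.0      # white EMG amplitude before band-passing, µV

    def __post_init__(self) -> None:
        for act in self.activities:
            if not 0.0 <= act.duty <= 1.0:
                raise ValueError(f"duty {act.duty} outside [0, 1]")
            if act.rms < 0:
                raise ValueError("rms amplitudes must be non-negative")
        if self.spindles is not None and not 0 <= self.spindles.n_segments <= 5:
            raise ValueError("spindle segment count must be in 0..5")
        if self.noise_sd < 0 or self.emg_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


def default_recipes() -> dict[str, StageRecipe]:
    """Stage recipe library satisfying the defining feature inequalities.

    Amplitudes follow the stage descriptions: NREM2 slow waves twice
    NREM1's amplitude and twice its duty cycle, TS spindles larger than
    NREM1's, EMG strictly ordered W > N1 > N2 > TS > R.  Wake carries the
    largest broadband background (movement and high-frequency activity)
    and only low-amplitude theta; REM's background sits slightly above
    the NREM floor, reflecting its desynchronized, wake-like EEG.  Both
    NREM stages keep faint slow-wave and spindle-band backgrounds over the
    whole epoch — sleeping cortex is never spectrally flat, and the index
    denominators assume delta/alpha power above the recording's floor.
    """
    delta_bg = BandActivity(0.5, 5.0, 1.5, 1.0)
    alpha_bg = BandActivity(10.5, 15.0, 1.5, 1.0)
    return {
        "W": StageRecipe(
            activities=(BandActivity(6.0, 9.0, 5.0, 1.0),),
            noise_sd=15.0, emg_sd=80.0,
        ),
        "N1": StageRecipe(
            activities=(BandActivity(0.5, 5.0, 42.0, 0.4), delta_bg, alpha_bg),
            spindles=SpindleActivity(10.5, 15.0, 28.0, 2),
            noise_sd=5.0, emg_sd=25.0,
        ),
        "N2": StageRecipe(
            activities=(BandActivity(0.5, 5.0, 85.0, 0.8), delta_bg, alpha_bg),
            noise_sd=5.0, emg_sd=15.0,
        ),
        "TS": StageRecipe(
            activities=(BandActivity(6.0, 9.0, 28.0, 1.0),),
            spindles=SpindleActivity(10.5, 15.0, 42.0, 3),
            noise_sd=5.0, emg_sd=10.0,
        ),
        "R": StageRecipe(
            activities=(BandActivity(6.0, 9.0, 28.0, 1.0),),
            noise_sd=7.0, emg_sd=3.0,
        ),
    }


def scale_noise(recipes: dict[str, StageRecipe], factor: float) -> dict[str, StageRecipe]:
    """Recipes with every broadband EEG background scaled (SNR degradation)."""
    return {
        stage: StageRecipe(
            activities=r.activities,
            spindles=r.spindles,
            noise_sd=r.noise_sd * factor,
            emg_sd=r.emg_sd,
        )
        for stage, r in recipes.items()
    }


@dataclass
class TransitionModel:
    """Row-stochastic per-epoch stage transition matrix over W,N1,N2,TS,R."""

    matrix: np.ndarray
    initial: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        k = len(STAGES_5)
        if self.matrix.shape != (k, k):
            raise ValueError(f"transition matrix must be {k}x{k}")
        if (self.matrix < 0).any() or np.any(np.abs(self.matrix.sum(axis=1) - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")
        if self.initial is None:
            self.initial = self.stationary()
        else:
            self.initial = np.asarray(self.initial, dtype=float)
            if self.initial.shape != (k,) or (self.initial < 0).any() \
                    or abs(self.initial.sum() - 1.0) > 1e-12:
                raise ValueError("initial distribution must be a length-5 simplex point")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, i]))
        return pi / pi.sum()


def default_transition_model() -> TransitionModel:
    """Bout structure favoring the physiological order W↔N1↔N2→TS→R→W."""
    m = np.array([
        # W     N1    N2    TS    R
        [0.80, 0.20, 0.00, 0.00, 0.00],   # W
        [0.05, 0.80, 0.15, 0.00, 0.00],   # N1
        [0.00, 0.10, 0.80, 0.10, 0.00],   # N2
        [0.00, 0.00, 0.05, 0.80, 0.15],   # TS
        [0.18, 0.00, 0.00, 0.02, 0.80],   # R
    ])
    return TransitionModel(matrix=m)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_hypnogram(
    n_epochs: int,
    model: Optional[TransitionModel] = None,
    seed=0,
    epoch_s: float = 10.0,
) -> Hypnogram:
    """Sample a ground-truth stage sequence from the Markov chain."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be at least 1")
    model = model or default_transition_model()
    rng = _rng(seed)
    k = len(STAGES_5)
    states = np.empty(n_epochs, dtype=int)
    states[0] = rng.choice(k, p=model.initial)
    for i in range(1, n_epochs):
        states[i] = rng.choice(k, p=model.matrix[states[i - 1]])
    return Hypnogram([STAGES_5[s] for s in states], epoch_s=epoch_s,
                     alphabet=STAGES_5)


def three_condition_hypnogram(n_per_condition: int = 200,
                              epoch_s: float = 10.0) -> Hypnogram:
    """Block design of wake, deep-NREM and REM epochs (training-style layout)."""
    labels = (["W"] * n_per_condition + ["N2"] * n_per_condition
              + ["R"] * n_per_condition)
    return Hypnogram(labels, epoch_s=epoch_s, alphabet=STAGES_5)


def _harmonics(n: int, rate: float, lo_hz: float, hi_hz: float, rms: float,
               rng: np.random.Generator, grid_hz: float = 0.5,
               t0: float = 0.0) -> np.ndarray:
    """Random-phase harmonic series on the analysis grid, at a target rms.

    Each grid frequency in [lo_hz, hi_hz) carries independent Gaussian
    cosine/sine amplitudes (a stationary Gaussian process with a flat comb
    spectrum), rescaled so the realized rms equals ``rms``.
    """
    if rms == 0.0 or n == 0:
        return np.zeros(n)
    freqs = np.arange(max(lo_hz, grid_hz), hi_hz - 1e-9, grid_hz)
    if freqs.size == 0:
        return np.zeros(n)
    t = t0 + np.arange(n) / rate
    a = rng.standard_normal(freqs.size)
    b = rng.standard_normal(freqs.size)
    x = a @ np.cos(2 * np.pi * np.outer(freqs, t)) \
        + b @ np.sin(2 * np.pi * np.outer(freqs, t))
    measured = float(np.sqrt(np.mean(x**2)))
    if measured == 0.0:
        return np.zeros(n)
    return x * (rms / measured)


def synthesize_epoch(
    stage: str,
    recipe: Optional[StageRecipe] = None,
    eeg_rate: float = 200.0,
    emg_rate: float = 500.0,
    seed=0,
    epoch_s: float = 10.0,
    segment_s: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One 10-s (eeg, emg) epoch for a stage; deterministic given the seed."""
    if recipe is None:
        library = default_recipes()
        if stage not in library:
            raise ValueError(f"unknown stage {stage!r}; no recipe available")
        recipe = library[stage]
    rng = _rng(seed)
    n_eeg = int(round(eeg_rate * epoch_s))
    n_emg = int(round(emg_rate * epoch_s))
    n_seg = int(round(eeg_rate * segment_s))
    segments = n_eeg // n_seg

    eeg = recipe.noise_sd * rng.standard_normal(n_eeg) if recipe.noise_sd else np.zeros(n_eeg)
    for act in recipe.activities:
        n_active = int(round(act.duty * segments)) * n_seg
        eeg[:n_active] += _harmonics(n_active, eeg_rate, act.lo_hz, act.hi_hz,
                                     act.rms, rng)
    if recipe.spindles is not None and recipe.spindles.n_segments > 0:
        sp = recipe.spindles
        chosen = rng.choice(segments, size=min(sp.n_segments, segments),
                            replace=False)
        for s in sorted(chosen):
            burst = _harmonics(n_seg, eeg_rate, sp.lo_hz, sp.hi_hz, sp.rms, rng)
            eeg[s * n_seg:(s + 1) * n_seg] += burst
    emg = recipe.emg_sd * rng.standard_normal(n_emg) if recipe.emg_sd else np.zeros(n_emg)
    return eeg, emg


def generate_recording(
    hypnogram: Hypnogram,
    recipes: Optional[dict[str, StageRecipe]] = None,
    eeg_rate: float = 200.0,
    emg_rate: float = 500.0,
    seed=0,
) -> Recording:
    """Concatenate per-epoch synthetic signals along a ground-truth hypnogram."""
    recipes = recipes or default_recipes()
    missing = set(hypnogram.labels) - set(recipes)
    if missing:
        raise ValueError(f"no recipe for stages: {sorted(missing)}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(hypnogram))
    eeg_parts, emg_parts = [], []
    for lab, child in zip(hypnogram.labels, children):
        eeg, emg = synthesize_epoch(
            lab, recipes[lab], eeg_rate, emg_rate,
            seed=np.random.default_rng(child), epoch_s=hypnogram.epoch_s,
        )
        eeg_parts.append(eeg)
        emg_parts.append(emg)
    return Recording(
        eeg=np.concatenate(eeg_parts), eeg_rate=eeg_rate,
        emg=np.concatenate(emg_parts), emg_rate=emg_rate,
        subject_id="synthetic", epoch_s=hypnogram.epoch_s,
    )


def generate_study(
    n_epochs: int = 600,
    seed=0,
    model: Optional[TransitionModel] = None,
    recipes: Optional[dict[str, StageRecipe]] = None,
) -> tuple[Recording, Hypnogram]:
    """Convenience: Markov hypnogram + recording from one seed."""
    ss = np.random.SeedSequence(seed)
    hyp_seed, rec_seed = ss.spawn(2)
    truth = generate_hypnogram(n_epochs, model=model,
                               seed=np.random.default_rng(hyp_seed))
    recording = generate_recording(truth, recipes=recipes, seed=rec_seed)
    return recording, truth
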