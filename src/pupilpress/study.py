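"""Comparative-study simulator: cohort, sessions, exclusions, measurements.

Emulates a four-session tonometer comparison on a healthy cohort. Each
participant is measured in four body positions — sitting (calibration),
supine, lying with legs raised 45°, sitting again — by the pupillometric
prototype followed immediately by a reference tonometer: Goldmann
applanation (GAT) while sitting, a rebound tonometer (iCare) while lying.
The first sitting measurement calibrates the prototype per eye and is
excluded from all comparisons.

The prototype-minus-reference deviation is modelled as a two-component
Gaussian mixture: a narrow core plus a wide tail. A single Gaussian
cannot simultaneously put ~80 % of deviations within ±1 mmHg and only
~90 % within ±3 mmHg; the default mixture (p=0.8, SDs 0.5 / 4.0 mmHg)
reproduces both fractions. Fixed position-dependent biases (−1 mmHg
supine, +1 mmHg legs raised) emulate the ~1 mmHg group-level offsets
between prototype and rebound-tonometer readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "TrueIOPModel",
    "DeviationModel",
    "Roster",
    "PairCounts",
    "build_cohort",
    "count_pairs",
    "simulate_measurements",
    "sample_deviations",
]

SESSIONS = ("sitting1", "supine", "raised_legs", "sitting2")
COMPARED_SESSIONS = ("supine", "raised_legs", "sitting2")
#: reference tonometer per session: GAT at the slit lamp requires sitting
REFERENCE_INSTRUMENT = {
    "sitting1": "GAT",
    "supine": "iCare",
    "raised_legs": "iCare",
    "sitting2": "GAT",
}
#: body position underlying each session (bias lookup key)
SESSION_POSITION = {
    "sitting1": "sitting",
    "supine": "supine",
    "raised_legs": "raised_legs",
    "sitting2": "sitting",
}

MEASUREMENT_COLUMNS = [
    "subject_id",
    "eye",
    "session",
    "instrument",
    "iop_mmHg",
    "is_calibration",
]


@dataclass(frozen=True)
class CohortConfig:
    """Recruitment and exclusion structure of the simulated cohort.

    Defaults: 20 recruited, 3 unable to cooperate, 1 yielding no data,
    1 further participant missing one eye, and 4 included participants
    unable to lie with raised legs -> 16 included participants, 31 eyes.
    """

    n_recruited: int = 20
    n_uncooperative: int = 3
    n_no_data_participants: int = 1
    n_missing_single_eyes: int = 1
    n_participants_skip_raised_legs: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_recruited,
            self.n_uncooperative,
            self.n_no_data_participants,
            self.n_missing_single_eyes,
            self.n_participants_skip_raised_legs,
        )
        if any(c < 0 for c in counts):
            raise ValueError("cohort counts must be >= 0")
        if self.n_included_participants < 0:
            raise ValueError("exclusions exceed recruitment")
        if self.n_missing_single_eyes > self.n_included_participants:
            raise ValueError("more missing single eyes than included participants")
        # raised-leg skippers are drawn from two-eyed participants only
        if (
            self.n_participants_skip_raised_legs
            > self.n_included_participants - self.n_missing_single_eyes
        ):
            raise ValueError("not enough two-eyed participants to skip raised legs")

    @property
    def n_included_participants(self) -> int:
        return self.n_recruited - self.n_uncooperative - self.n_no_data_participants

    @property
    def n_included_eyes(self) -> int:
        return 2 * self.n_included_participants - self.n_missing_single_eyes


@dataclass(frozen=True)
class TrueIOPModel:
    """Distribution of the underlying sitting IOP and reference noise.

    True IOP per eye is Normal(mean, sd²) clipped to [low, high] mmHg;
    each reference reading adds Gaussian instrument noise.
    """

    mean_mmHg: float = 18.25
    sd_mmHg: float = 2.2
    low_mmHg: float = 9.0
    high_mmHg: float = 23.0
    reference_noise_sd_mmHg: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_mmHg <= 0 or self.reference_noise_sd_mmHg < 0:
            raise ValueError("sd_mmHg must be > 0 and reference noise >= 0")
        if not self.low_mmHg < self.high_mmHg:
            raise ValueError("require low_mmHg < high_mmHg")


def _default_biases() -> dict:
    return {"sitting": 0.0, "supine": -1.0, "raised_legs": 1.0}


@dataclass(frozen=True)
class DeviationModel:
    """Two-component Gaussian mixture for prototype-minus-reference error.

    With probability ``p_core`` the deviation is N(0, sd_core²), else
    N(0, sd_tail²); a fixed per-position bias is added on top.
    """

    p_core: float = 0.8
    sd_core_mmHg: float = 0.5
    sd_tail_mmHg: float = 4.0
    group_bias_mmHg: dict = field(default_factory=_default_biases)

    def __post_init__(self) -> None:
        if not 0 <= self.p_core <= 1:
            raise ValueError("p_core must be in [0, 1]")
        if self.sd_core_mmHg < 0 or self.sd_tail_mmHg < 0:
            raise ValueError("mixture SDs must be >= 0")

    def zero_bias(self) -> "DeviationModel":
        """Copy of the model with all position biases set to zero."""
        return DeviationModel(
            p_core=self.p_core,
            sd_core_mmHg=self.sd_core_mmHg,
            sd_tail_mmHg=self.sd_tail_mmHg,
            group_bias_mmHg={k: 0.0 for k in self.group_bias_mmHg},
        )


@dataclass
class Roster:
    """Who is in the study: one row per eye with its sessions."""

    eyes: pd.DataFrame  # columns: subject_id, eye, has_raised_legs

    @property
    def n_participants(self) -> int:
        return self.eyes["subject_id"].nunique()

    @property
    def n_eyes(self) -> int:
        return len(self.eyes)

    def sessions_of(self, row: pd.Series) -> tuple[str, ...]:
        if row["has_raised_legs"]:
            return SESSIONS
        return tuple(s for s in SESSIONS if s != "raised_legs")


@dataclass(frozen=True)
class PairCounts:
    """Measurement-pair accounting: each session of each eye is one pair."""

    total: int
    calibration: int
    compared_supine: int
    compared_raised_legs: int
    compared_sitting2: int

    @property
    def compared(self) -> int:
        return self.compared_supine + self.compared_raised_legs + self.compared_sitting2


def build_cohort(config: CohortConfig | None = None) -> Roster:
    """Draw the cohort roster: exclusions and raised-leg skips under seed.

    Uncooperative and no-data participants are removed entirely; one eye
    is removed from each single-eye-missing participant; raised-leg
    skippers are drawn from included participants with both eyes.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    subjects = [f"P{i + 1:02d}" for i in range(config.n_recruited)]

    n_excl = config.n_uncooperative + config.n_no_data_participants
    excluded = set(rng.choice(subjects, size=n_excl, replace=False)) if n_excl else set()
    included = [s for s in subjects if s not in excluded]

    one_eyed = (
        set(rng.choice(included, size=config.n_missing_single_eyes, replace=False))
        if config.n_missing_single_eyes
        else set()
    )
    two_eyed = [s for s in included if s not in one_eyed]
    skippers = (
        set(
            rng.choice(
                two_eyed, size=config.n_participants_skip_raised_legs, replace=False
            )
        )
        if config.n_participants_skip_raised_legs
        else set()
    )

    rows = []
    for s in included:
        eyes = ["OD"] if s in one_eyed else ["OD", "OS"]
        if s in one_eyed and rng.random() < 0.5:
            eyes = ["OS"]
        for e in eyes:
            rows.append({"subject_id": s, "eye": e, "has_raised_legs": s not in skippers})
    frame = pd.DataFrame(rows, columns=["subject_id", "eye", "has_raised_legs"])
    return Roster(eyes=frame)


def count_pairs(roster: Roster) -> PairCounts:
    """Tally measurement pairs by role (one prototype+reference pair per
    eye per session; the first sitting pair is the calibration pair)."""
    if roster.n_eyes == 0:
        return PairCounts(0, 0, 0, 0, 0)
    n_eyes = roster.n_eyes
    n_raised = int(roster.eyes["has_raised_legs"].sum())
    return PairCounts(
        total=3 * n_eyes + n_raised,
        calibration=n_eyes,
        compared_supine=n_eyes,
        compared_raised_legs=n_raised,
        compared_sitting2=n_eyes,
    )


def sample_deviations(
    model: DeviationModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` zero-bias deviations from the mixture."""
    core = rng.random(n) < model.p_core
    sd = np.where(core, model.sd_core_mmHg, model.sd_tail_mmHg)
    return sd * rng.standard_normal(n)


def simulate_measurements(
    roster: Roster,
    true_iop_model: TrueIOPModel | None = None,
    deviation_model: DeviationModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the full paired measurement table for a roster.

    Per eye: a true sitting IOP is drawn once; each session's reference
    reading is truth plus instrument noise; each compared prototype
    reading is the reference reading plus the position bias plus a
    mixture deviation. Calibration-session prototype readings equal the
    reference reading (the prototype is defined to agree at calibration).

    Returns a long-format table with columns
    ``subject_id, eye, session, instrument, iop_mmHg, is_calibration``.
    """
    true_iop_model = true_iop_model or TrueIOPModel()
    deviation_model = deviation_model or DeviationModel()
    rng = np.random.default_rng(seed)

    rows = []
    for _, eye_row in roster.eyes.iterrows():
        true_iop = float(
            np.clip(
                rng.normal(true_iop_model.mean_mmHg, true_iop_model.sd_mmHg),
                true_iop_model.low_mmHg,
                true_iop_model.high_mmHg,
            )
        )
        for session in roster.sessions_of(eye_row):
            ref = true_iop + rng.normal(0.0, true_iop_model.reference_noise_sd_mmHg)
            is_cal = session == "sitting1"
            if is_cal:
                proto = ref
            else:
                bias = deviation_model.group_bias_mmHg.get(
                    SESSION_POSITION[session], 0.0
                )
                dev = float(sample_deviations(deviation_model, 1, rng)[0])
                proto = ref + bias + dev
            for instrument, value in (
                ("prototype", proto),
                (REFERENCE_INSTRUMENT[session], ref),
            ):
                rows.append(
                    {
                        "subject_id": eye_row["subject_id"],
                        "eye": eye_row["eye"],
                        "session": session,
                        "instrument": instrument,
                        "iop_mmHg": value,
                        "is_calibration": is_cal,
                    }
                )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
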