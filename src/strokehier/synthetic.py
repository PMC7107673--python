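"""Synthetic study data: tabular stroke cohorts and pseudo-CT phantoms.

The cohort generator emulates the marginal structure of a 300-patient acute
ischemic stroke registry: 43.3% large-vessel-occlusion (LVO) prevalence,
class-conditional demographics/symptoms/vitals, literal ``Unknown`` levels for
unascertained categoricals, and genuinely missing continuous vitals. Linked
variable blocks (limb/facial laterality, smoking status, GCS subscales) are
sampled jointly so each record is internally consistent — e.g. the GCS total
is the sum of its eye/verbal/motor subscales and side-specific weakness only
occurs when the parent symptom is present.

The phantom generator builds 512x512 axial pseudo-CT volumes: an elliptical
brain of ~30 HU inside a >100 HU skull ring, optionally carrying a bright
2–6 px intravascular dot (the hyperdense MCA sign, 40–80 HU so it survives the
[20, 80] attenuation window) inside a proximal-Sylvian zone of one hemisphere
ROI box, plus calcification-like distractor dots whose intensity falls outside
the window. Sign presence is drawn from class-conditional probabilities that
reproduce the sign/LVO contingency (P(LVO | sign) ~ 0.97).
"""

from __future__ import annotations

import copy
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import CTVolume, PreprocessConfig

__all__ = [
    "CohortConfig",
    "PhantomConfig",
    "PhantomStudy",
    "LEVEL1_COLUMNS",
    "LEVEL2_COLUMNS",
    "CONTINUOUS_COLUMNS",
    "default_feature_spec",
    "generate_cohort",
    "generate_phantom",
    "generate_phantom_cohort",
    "simulate_deep_features",
    "sample_sign",
    "substream",
    "write_cohort_csv",
    "read_cohort_csv",
]

LEVEL1_COLUMNS = [
    "age",
    "gender",
    "limb_weakness",
    "left_limb_weakness",
    "right_limb_weakness",
    "facial_weakness",
    "left_facial_weakness",
    "right_facial_weakness",
    "speech_deficit",
]

LEVEL2_COLUMNS = LEVEL1_COLUMNS + [
    "gcs_total",
    "gcs_eye",
    "gcs_verbal",
    "gcs_motor",
    "diastolic_bp",
    "systolic_bp",
    "diabetes",
    "hypertension",
    "smoker",
    "current_smoker",
    "ex_smoker",
    "atherosclerosis",
    "atrial_fibrillation",
    "cardioembolism",
    "valvular_heart_disease",
]

CONTINUOUS_COLUMNS = [
    "age",
    "gcs_total",
    "gcs_eye",
    "gcs_verbal",
    "gcs_motor",
    "diastolic_bp",
    "systolic_bp",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent random substream derived from one seed."""
    return np.random.default_rng([seed, zlib.crc32(name.encode())])


def _sd_from_ci(lo: float, hi: float, n_obs: int) -> float:
    """Back-solve a sample SD from a normal-theory 95% CI of the mean."""
    return (hi - lo) / 2.0 * np.sqrt(n_obs) / 1.959964


def default_feature_spec() -> dict:
    """Class-conditional sampling parameters for every cohort variable.

    Continuous variables carry per-class means and SDs (SDs back-solved from
    95% CIs of the mean at the observed-case counts); categorical variables
    carry per-class level probabilities whose masses sum to one, with linked
    blocks (laterality, smoking, GCS) expressed through conditional stages.
    Keys ``True``/``False`` index the LVO-positive/negative class.
    """
    spec = {
        "age": {
            "kind": "normal",
            "mean": {True: 79.69, False: 73.19},
            "sd": {True: _sd_from_ci(77.55, 81.84, 130), False: _sd_from_ci(71.15, 75.24, 170)},
        },
        "gender": {
            "kind": "categorical",
            "levels": ["female", "male"],
            "p": {True: [84 / 130, 46 / 130], False: [76 / 170, 94 / 170]},
        },
        # limb weakness: presence, then laterality (left-only / right-only /
        # both) chosen so the side marginals match the presence marginal
        "limb": {
            "kind": "limb_block",
            "p_yes": {True: 129 / 130, False: 126 / 170},
            "p_side": {  # left-only, right-only, both — conditional on yes
                True: [56 / 129, 70 / 129, 3 / 129],
                False: [56 / 126, 63 / 126, 7 / 126],
            },
        },
        # facial weakness: ascertained at all, then presence, then side;
        # when unascertained all three facial variables are Unknown
        "facial": {
            "kind": "facial_block",
            "p_known": {True: 52 / 130, False: 97 / 170},
            "p_yes_given_known": {True: 41 / 52, False: 44 / 97},
            "p_left_given_yes": {True: 19 / 41, False: 25 / 44},
        },
        "speech_deficit": {
            "kind": "categorical",
            "levels": ["yes", "no"],
            "p": {True: [62 / 130, 68 / 130], False: [72 / 170, 98 / 170]},
        },
        # GCS subscales sampled as rounded, range-clipped normals; the total
        # is derived as their sum, then each block is masked at its own
        # missingness rate
        "gcs": {
            "kind": "gcs_block",
            "eye": {
                "mean": {True: 3.18, False: 3.83},
                "sd": {True: _sd_from_ci(2.96, 3.41, 98), False: _sd_from_ci(3.72, 3.93, 145)},
            },
            "verbal": {
                "mean": {True: 2.44, False: 4.25},
                "sd": {True: _sd_from_ci(2.14, 2.74, 98), False: _sd_from_ci(4.02, 4.48, 145)},
            },
            "motor": {
                "mean": {True: 5.16, False: 5.70},
                "sd": {True: _sd_from_ci(4.96, 5.36, 98), False: _sd_from_ci(5.56, 5.85, 145)},
            },
            "p_missing_subscales": {True: 32 / 130, False: 25 / 170},
            "p_missing_total": {True: 9 / 130, False: 15 / 170},
        },
        # blood pressures are jointly observed or jointly missing
        "bp": {
            "kind": "bp_block",
            "diastolic": {
                "mean": {True: 84.50, False: 83.90},
                "sd": {True: _sd_from_ci(80.71, 88.29, 74), False: _sd_from_ci(80.99, 86.82, 92)},
            },
            "systolic": {
                "mean": {True: 154.82, False: 162.40},
                "sd": {True: _sd_from_ci(148.62, 161.02, 74), False: _sd_from_ci(157.46, 167.34, 92)},
            },
            "p_missing": {True: 56 / 130, False: 78 / 170},
        },
        "diabetes": {
            "kind": "categorical",
            "levels": ["yes", "no"],
            "p": {True: [30 / 130, 100 / 130], False: [45 / 170, 125 / 170]},
        },
        "hypertension": {
            "kind": "categorical",
            "levels": ["yes", "no"],
            "p": {True: [89 / 130, 41 / 130], False: [118 / 170, 52 / 170]},
        },
        # smoking: status ascertained at all, then ever-smoker, then
        # current vs quit; unascertained leaves all three smoking
        # variables Unknown
        "smoking": {
            "kind": "smoking_block",
            "p_known": {True: 77 / 130, False: 117 / 170},
            "p_smoker_given_known": {True: 15 / 77, False: 47 / 117},
            "p_current_given_smoker": {True: 8 / 15, False: 22 / 47},
        },
        # registry comorbidity flags are recorded as yes or not-recorded
        "atherosclerosis": {
            "kind": "categorical",
            "levels": ["yes", None],
            "p": {True: [3 / 130, 127 / 130], False: [6 / 170, 164 / 170]},
        },
        "atrial_fibrillation": {
            "kind": "categorical",
            "levels": ["yes", None],
            "p": {True: [48 / 130, 82 / 130], False: [32 / 170, 138 / 170]},
        },
        "cardioembolism": {
            "kind": "categorical",
            "levels": ["yes", None],
            "p": {True: [8 / 130, 122 / 130], False: [2 / 170, 168 / 170]},
        },
        "valvular_heart_disease": {
            "kind": "categorical",
            "levels": ["yes", None],
            "p": {True: [61 / 130, 69 / 130], False: [86 / 170, 84 / 170]},
        },
    }
    return spec


@dataclass
class CohortConfig:
    """Configuration for tabular cohort simulation."""

    n_patients: int = 300
    lvo_prevalence: float = 130 / 300
    feature_spec: dict = field(default_factory=default_feature_spec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.lvo_prevalence <= 1.0:
            raise ValueError("lvo_prevalence must lie in [0, 1]")
        _validate_spec(self.feature_spec)


def _validate_spec(spec: dict) -> None:
    for name, desc in spec.items():
        if desc["kind"] == "categorical":
            for cls, p in desc["p"].items():
                if abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(f"probabilities for {name!r} (class {cls}) do not sum to 1")
                if any(q < 0 for q in p):
                    raise ValueError(f"negative probability for {name!r}")
        for key in ("p_yes", "p_known", "p_yes_given_known", "p_left_given_yes",
                    "p_smoker_given_known", "p_current_given_smoker",
                    "p_missing", "p_missing_subscales", "p_missing_total"):
            if key in desc:
                for cls, p in desc[key].items():
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(f"{name}.{key} (class {cls}) outside [0, 1]")
        if "p_side" in desc:
            for cls, p in desc["p_side"].items():
                if abs(sum(p) - 1.0) > 1e-9:
                    raise ValueError(f"{name}.p_side (class {cls}) does not sum to 1")


def _pick(rng: np.random.Generator, n: int, levels: list, probs: list[float]) -> np.ndarray:
    out = rng.choice(len(levels), size=n, p=probs)
    return np.array([np.nan if levels[i] is None else levels[i] for i in out], dtype=object)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Simulate one labelled cohort.

    Returns a DataFrame with an ``id`` column, a boolean ``lvo`` label, the
    Level-1/Level-2 variables, NaN for missing cells (continuous and
    categorical alike; ``Unknown`` encoding is a downstream modelling step),
    and deterministic content given ``config.seed``.
    """
    config = config or CohortConfig()
    spec = config.feature_spec
    rng = substream(config.seed, "cohort")
    n = config.n_patients

    lvo = rng.random(n) < config.lvo_prevalence
    df = pd.DataFrame({"id": [f"P{i:05d}" for i in range(n)], "lvo": lvo})
    if n == 0:
        for col in LEVEL2_COLUMNS:
            df[col] = pd.Series(dtype=object if col not in CONTINUOUS_COLUMNS else float)
        return df

    def per_class(fn) -> np.ndarray:
        """Evaluate a class-conditional sampler over the whole cohort."""
        out = None
        for cls in (True, False):
            idx = np.flatnonzero(lvo == cls)
            vals = fn(cls, idx.size)
            if out is None:
                out = np.empty(n, dtype=np.asarray(vals).dtype if np.asarray(vals).dtype.kind != "U" else object)
            out[idx] = vals
        return out

    # --- continuous: age ---
    a = spec["age"]
    df["age"] = per_class(lambda c, m: rng.normal(a["mean"][c], a["sd"][c], m))

    # --- simple categoricals ---
    for name, col in [("gender", "gender"), ("speech_deficit", "speech_deficit"),
                      ("diabetes", "diabetes"), ("hypertension", "hypertension"),
                      ("atherosclerosis", "atherosclerosis"),
                      ("atrial_fibrillation", "atrial_fibrillation"),
                      ("cardioembolism", "cardioembolism"),
                      ("valvular_heart_disease", "valvular_heart_disease")]:
        d = spec[name]
        df[col] = per_class(lambda c, m, d=d: _pick(rng, m, d["levels"], d["p"][c]))

    # --- limb weakness block ---
    lb = spec["limb"]
    limb = per_class(lambda c, m: (rng.random(m) < lb["p_yes"][c]))
    side = per_class(lambda c, m: rng.choice(3, size=m, p=lb["p_side"][c]))
    left = np.where(limb & ((side == 0) | (side == 2)), "yes", "no").astype(object)
    right = np.where(limb & ((side == 1) | (side == 2)), "yes", "no").astype(object)
    df["limb_weakness"] = np.where(limb, "yes", "no").astype(object)
    df["left_limb_weakness"] = left
    df["right_limb_weakness"] = right

    # --- facial weakness block (shared Unknown mass) ---
    fb = spec["facial"]
    known = per_class(lambda c, m: rng.random(m) < fb["p_known"][c])
    yes = per_class(lambda c, m: rng.random(m) < fb["p_yes_given_known"][c]) & known
    left_side = per_class(lambda c, m: rng.random(m) < fb["p_left_given_yes"][c])
    facial = np.where(yes, "yes", "no").astype(object)
    fleft = np.where(yes & left_side, "yes", "no").astype(object)
    fright = np.where(yes & ~left_side, "yes", "no").astype(object)
    facial[~known] = np.nan
    fleft[~known] = np.nan
    fright[~known] = np.nan
    df["facial_weakness"] = facial
    df["left_facial_weakness"] = fleft
    df["right_facial_weakness"] = fright

    # --- GCS block: subscales first, total derived ---
    g = spec["gcs"]

    def sub(scale: str, lo: int, hi: int) -> np.ndarray:
        p = g[scale]
        raw = per_class(lambda c, m: rng.normal(p["mean"][c], p["sd"][c], m))
        return np.clip(np.rint(raw), lo, hi)

    eye, verbal, motor = sub("eye", 1, 4), sub("verbal", 1, 5), sub("motor", 1, 6)
    total = eye + verbal + motor
    miss_sub = per_class(lambda c, m: rng.random(m) < g["p_missing_subscales"][c])
    miss_tot = per_class(lambda c, m: rng.random(m) < g["p_missing_total"][c])
    df["gcs_eye"] = np.where(miss_sub, np.nan, eye)
    df["gcs_verbal"] = np.where(miss_sub, np.nan, verbal)
    df["gcs_motor"] = np.where(miss_sub, np.nan, motor)
    df["gcs_total"] = np.where(miss_tot, np.nan, total)

    # --- blood pressure block (jointly missing) ---
    b = spec["bp"]
    dbp = per_class(lambda c, m: rng.normal(b["diastolic"]["mean"][c], b["diastolic"]["sd"][c], m))
    sbp = per_class(lambda c, m: rng.normal(b["systolic"]["mean"][c], b["systolic"]["sd"][c], m))
    dbp, sbp = np.maximum(dbp, 1.0), np.maximum(sbp, 1.0)
    miss_bp = per_class(lambda c, m: rng.random(m) < b["p_missing"][c])
    df["diastolic_bp"] = np.where(miss_bp, np.nan, dbp)
    df["systolic_bp"] = np.where(miss_bp, np.nan, sbp)

    # smoking block: unascertained -> all three Unknown (NaN here)
    s = spec["smoking"]
    sknown = per_class(lambda c, m: rng.random(m) < s["p_known"][c])
    smoker = per_class(lambda c, m: rng.random(m) < s["p_smoker_given_known"][c]) & sknown
    current = per_class(lambda c, m: rng.random(m) < s["p_current_given_smoker"][c]) & smoker
    smk = np.where(smoker, "yes", "no").astype(object)
    cur = np.where(current, "yes", "no").astype(object)
    ex = np.where(smoker & ~current, "yes", "no").astype(object)
    for arr in (smk, cur, ex):
        arr[~sknown] = np.nan
    df["smoker"], df["current_smoker"], df["ex_smoker"] = smk, cur, ex

    return df[["id", "lvo"] + LEVEL2_COLUMNS]


def override_spec(base: dict, **overrides: dict) -> dict:
    """Deep-copy a feature spec and replace whole variable entries."""
    spec = copy.deepcopy(base)
    spec.update(overrides)
    _validate_spec(spec)
    return spec


# ---------------------------------------------------------------------------
# Phantom volumes
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry and intensity model for pseudo-CT phantom volumes."""

    n_slices: int = 10
    shape: tuple[int, int] = (512, 512)
    pixel_mm: float = 0.426
    slice_mm: float = 5.0
    background_intensity: float = 30.0
    lesion_intensity_range: tuple[float, float] = (45.0, 75.0)
    skull_intensity: float = 150.0
    noise_sd: float = 2.0
    distractor_rate: float = 2.0
    p_sign_given_lvo: float = 68 / 130
    p_sign_given_nolvo: float = 6 / 170
    lesion_radius_range: tuple[int, int] = (2, 6)
    placement_radius: int = 20
    brain_semiaxes: tuple[float, float] = (190.0, 150.0)
    skull_thickness: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_intensity_range
        if not (20.0 < lo and hi <= 80.0):
            raise ValueError("lesion intensities must lie inside the (20, 80] window")
        if 20.0 < self.skull_intensity <= 80.0:
            raise ValueError("skull intensity must lie outside the (20, 80] window")
        pre = PreprocessConfig()
        if self.n_slices < pre.slice_range[1]:
            raise ValueError(
                f"n_slices={self.n_slices} cannot cover candidate slices {pre.slice_range}"
            )


@dataclass
class PhantomStudy:
    """One phantom patient: volume, voxel-level lesion truth, and labels."""

    volume: CTVolume
    truth_mask: np.ndarray
    has_sign: bool
    label_lvo: bool
    lesion_center: tuple[int, int, int] | None = None  # (slice, row, col)

    def __post_init__(self) -> None:
        if self.has_sign != bool(self.truth_mask.any()):
            raise ValueError("truth_mask must be nonempty iff has_sign")


def sample_sign(label_lvo: bool, config: PhantomConfig, rng: np.random.Generator) -> bool:
    """Draw hyperdense-sign presence from its class-conditional probability."""
    p = config.p_sign_given_lvo if label_lvo else config.p_sign_given_nolvo
    return bool(rng.random() < p)


def _roi_centers(pre: PreprocessConfig) -> list[tuple[int, int]]:
    centers = []
    for box in (pre.box_a, pre.box_b):
        (r0, r1), (c0, c1) = box
        centers.append(((r0 + r1) // 2, (c0 + c1) // 2))
    return centers


def generate_phantom(
    config: PhantomConfig,
    label_lvo: bool,
    rng: np.random.Generator,
    patient_id: str = "phantom",
    has_sign: bool | None = None,
) -> PhantomStudy:
    """Build one phantom volume with optional hyperdense-MCA-sign lesion.

    The lesion is a 2–6 px radius dot of in-window intensity placed inside a
    fixed disc around one hemisphere ROI-box centre, on one of the candidate
    slices. Distractors are small out-of-window bright dots (calcification
    mimics) placed anywhere in the brain, in expectation ``distractor_rate``
    per volume.
    """
    pre = PreprocessConfig()
    nr, nc = config.shape
    vol = np.zeros((config.n_slices, nr, nc), dtype=np.float32)
    rows, cols = np.ogrid[:nr, :nc]
    cr, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    ar, ac = config.brain_semiaxes
    d2 = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2
    brain = d2 <= 1.0
    skull = (d2 > 1.0) & (
        ((rows - cr) / (ar + config.skull_thickness)) ** 2
        + ((cols - cc) / (ac + config.skull_thickness)) ** 2
        <= 1.0
    )
    for s in range(config.n_slices):
        sl = np.zeros((nr, nc), dtype=np.float32)
        sl[brain] = config.background_intensity + rng.normal(0, config.noise_sd, int(brain.sum()))
        sl[skull] = config.skull_intensity
        vol[s] = sl

    truth = np.zeros_like(vol, dtype=bool)
    if has_sign is None:
        has_sign = sample_sign(label_lvo, config, rng)
    lesion_center = None
    if has_sign:
        hemi = int(rng.integers(2))
        hr, hc = _roi_centers(pre)[hemi]
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, config.placement_radius)
        lr, lc = int(round(hr + rad * np.cos(ang))), int(round(hc + rad * np.sin(ang)))
        ls = int(rng.integers(pre.slice_indices[0], pre.slice_indices[-1] + 1))
        r = int(rng.integers(config.lesion_radius_range[0], config.lesion_radius_range[1] + 1))
        inten = rng.uniform(*config.lesion_intensity_range)
        disc = (rows - lr) ** 2 + (cols - lc) ** 2 <= r**2
        vol[ls][disc] = inten
        truth[ls][disc] = True
        lesion_center = (ls, lr, lc)

    n_distract = rng.poisson(config.distractor_rate)
    placed = 0
    while placed < n_distract:
        ds = int(rng.integers(config.n_slices))
        dr = int(rng.integers(nr))
        dc = int(rng.integers(nc))
        if not brain[dr, dc]:
            continue
        if lesion_center is not None and ds == lesion_center[0]:
            if (dr - lesion_center[1]) ** 2 + (dc - lesion_center[2]) ** 2 < 15**2:
                continue
        r = int(rng.integers(1, 4))
        inten = rng.uniform(90.0, 200.0)
        disc = (rows - dr) ** 2 + (cols - dc) ** 2 <= r**2
        vol[ds][disc & brain & ~truth[ds]] = inten
        placed += 1

    volume = CTVolume(vol, pixel_mm=config.pixel_mm, slice_mm=config.slice_mm, id=patient_id)
    return PhantomStudy(volume=volume, truth_mask=truth, has_sign=bool(has_sign),
                        label_lvo=bool(label_lvo), lesion_center=lesion_center)


def generate_phantom_cohort(
    labels: list[bool] | np.ndarray,
    config: PhantomConfig | None = None,
) -> list[PhantomStudy]:
    """One phantom per label, each from its own named substream so partial
    re-runs reproduce individual studies."""
    config = config or PhantomConfig()
    studies = []
    for i, lab in enumerate(labels):
        rng = substream(config.seed, f"phantom-{i:05d}")
        studies.append(generate_phantom(config, bool(lab), rng, patient_id=f"P{i:05d}"))
    return studies


def phantom_training_patches(
    n_phantoms: int,
    config: PhantomConfig | None = None,
    neg_per_pos: int = 2,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Segmentation training data from ``n_phantoms`` sign-positive phantoms.

    Each phantom runs through the full pre-processing pipeline; its
    lesion-positive patch is kept together with ``neg_per_pos`` randomly
    chosen lesion-free patches, yielding a class balance a small network can
    learn from (per-batch hard-negative mining handles the rest). Returns
    (patches, boolean masks).
    """
    from .preprocess import crop_roi, preprocess_volume

    config = config or PhantomConfig()
    sel_rng = substream(config.seed, "patch-selection")
    patches: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for i in range(n_phantoms):
        rng = substream(config.seed, f"phantom-{i:05d}")
        study = generate_phantom(config, True, rng, patient_id=f"S{i:04d}", has_sign=True)
        stack = preprocess_volume(study.volume)
        mstack = crop_roi(CTVolume(study.truth_mask.astype(np.float32), id=study.volume.id))
        m = [p > 0.5 for p in mstack.patches]
        pos = [k for k in range(12) if m[k].any()]
        neg = [k for k in range(12) if not m[k].any()]
        keep = pos + list(sel_rng.choice(neg, size=min(len(neg), neg_per_pos * len(pos)),
                                         replace=False))
        for k in keep:
            patches.append(stack.patches[k])
            masks.append(m[k])
    return patches, masks


# ---------------------------------------------------------------------------
# Simulated deep-feature block
# ---------------------------------------------------------------------------

def simulate_deep_features(
    cohort: pd.DataFrame,
    n_channels: int = 64,
    n_informative: int = 8,
    effect: float = 1.5,
    seed: int = 0,
    phantom_config: PhantomConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Emulate the segmentation network's pooled feature block at cohort scale.

    For each patient a hyperdense-sign indicator is drawn from the
    class-conditional sign probabilities; feature channels are unit-variance
    Gaussians, with ``n_informative`` channels shifted by ``effect`` when the
    sign is present. This mirrors what a trained sign segmenter contributes —
    imaging channels informative about LVO only through the sign — without
    rendering volumes. Returns (features indexed by patient id, sign series).
    """
    phantom_config = phantom_config or PhantomConfig()
    rng = substream(seed, "deep-features")
    p = np.where(cohort["lvo"].to_numpy(dtype=bool),
                 phantom_config.p_sign_given_lvo, phantom_config.p_sign_given_nolvo)
    sign = rng.random(len(cohort)) < p
    X = rng.normal(0.0, 1.0, size=(len(cohort), n_channels))
    X[:, :n_informative] += effect * sign[:, None]
    cols = [f"f{j + 1:04d}" for j in range(n_channels)]
    feats = pd.DataFrame(X, columns=cols, index=cohort["id"].to_numpy())
    return feats, pd.Series(sign, index=cohort["id"].to_numpy(), name="has_sign")


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """One header row; empty cell = missing (continuous and categorical)."""
    cohort.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["lvo"] = df["lvo"].astype(bool)
    for col in LEVEL2_COLUMNS:
        if col not in CONTINUOUS_COLUMNS:
            df[col] = df[col].astype(object)
            df.loc[df[col].isna(), col] = np.nan
    return df


def write_phantom_study(study: PhantomStudy, out_dir) -> None:
    """Persist one phantom as NIfTI volume + mask pair."""
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    pid = study.volume.id
    affine = np.diag([study.volume.pixel_mm, study.volume.pixel_mm, study.volume.slice_mm, 1.0])
    # store as (rows, cols, slices) per NIfTI convention
    vox = np.transpose(study.volume.voxels, (1, 2, 0))
    msk = np.transpose(study.truth_mask.astype(np.uint8), (1, 2, 0))
    nib.save(nib.Nifti1Image(vox, affine), os.path.join(out_dir, f"{pid}_ct.nii"))
    nib.save(nib.Nifti1Image(msk, affine), os.path.join(out_dir, f"{pid}_mask.nii"))


def read_phantom_volume(path, patient_id: str = "", pixel_mm: float = 0.426, slice_mm: float = 5.0) -> CTVolume:
    import nibabel as nib

    img = nib.load(path)
    vox = np.transpose(np.asarray(img.dataobj, dtype=np.float32), (2, 0, 1))
    return CTVolume(vox, pixel_mm=pixel_mm, slice_mm=slice_mm, id=patient_id)
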