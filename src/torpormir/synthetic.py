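"""Synthetic data generation with known ground truth.

Every stage of the pipeline is exercised against data produced here: a
cross-species probe-level expression matrix with a heteroscedastic noise
floor and planted family-coherent group effects, qPCR Ct tables, western-blot
densitometry tables, WST-1 absorbance tables, dual-luciferase luminescence
tables, and small sequence fixtures for the seed scanner.

Noise model for the array
-------------------------
Each intensity is drawn as::

    value = max(eps, Normal(mu, sd(mu))),   sd(mu) = max(background_sd, cv * mu)

i.e. multiplicative measurement noise with coefficient of variation ``cv``
above an additive background-dominated noise floor. The coefficient of
variation of the draw is therefore ``background_sd / mu`` (falling
hyperbolically) below ``nu = background_sd / cv`` and the constant ``cv``
above it, which is exactly the non-linear-then-linear CV~mean shape the
noise-floor estimator looks for, with its changepoint at ``nu``.

Expressed probes get true means log-uniform across a wide range above the
floor; unexpressed probes sit at sub-floor background levels so that the
non-informative filter can remove them. Planted differential families are
always expressed, comfortably above the floor, with the configured signed
fold applied to the LH group mean (negative fold = lower in LH).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "ArrayConfig",
    "ArrayTruth",
    "generate_array",
    "QpcrConfig",
    "generate_qpcr",
    "AssayConfig",
    "generate_assay_tables",
    "random_mature_mirna",
    "target_with_planted_sites",
    "synthetic_family_table",
]

_EPS = 1e-6


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayConfig:
    """Settings for :func:`generate_array`.

    Defaults mirror the scale of the study design this package targets:
    a ~20,180-probe multi-species array, 6 samples per condition. Tests and
    simulations typically run at 1,000-5,000 probes.
    """

    n_probes: int = 20_180
    n_species: int = 131
    n_families: int = 600
    fraction_expressed: float = 0.5
    noise_floor: float = 50.0  # nu_true, intensity units
    planted_families: tuple[tuple[str, float], ...] = ()
    cv_above_floor: float = 0.15
    background_sd: float | None = None  # default: cv_above_floor * noise_floor
    n_per_group: int = 6
    groups: tuple[str, str] = ("ACR", "LH")
    # log-uniform true-mean ranges, as multiples of the noise floor
    expressed_mean_range: tuple[float, float] = (0.6, 100.0)
    unexpressed_mean_range: tuple[float, float] = (0.1, 0.6)
    planted_mean_range: tuple[float, float] = (4.0, 40.0)
    min_planted_members: int = 3
    seed: int = 0

    @property
    def effective_background_sd(self) -> float:
        if self.background_sd is not None:
            return self.background_sd
        return self.cv_above_floor * self.noise_floor


@dataclass
class ArrayTruth:
    """Ground truth behind a generated matrix."""

    noise_floor: float
    probe_truth: pd.DataFrame  # index probe_id: true_mean_ACR, true_mean_LH,
    #                            family, species, is_differential, planted_fold
    design: dict
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "noise_floor": self.noise_floor,
            "design": self.design,
            "seed": self.seed,
            "probe_truth": self.probe_truth.reset_index().to_dict(orient="list"),
        }


def _species_codes(n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic pool of distinct three-letter species prefixes."""
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    codes: list[str] = []
    i = 0
    while len(codes) < n:
        a, b, c = i // 676 % 26, i // 26 % 26, i % 26
        code = alphabet[a] + alphabet[b] + alphabet[c]
        i += 1
        codes.append(code)
    return codes


def _family_pool(config: ArrayConfig) -> list[str]:
    planted = [fam for fam, _ in config.planted_families]
    pool = list(planted)
    if "let-7" not in pool and len(pool) < config.n_families:
        pool.append("let-7")
    used_numbers = set()
    for fam in pool:
        tail = fam.rsplit("-", 1)[-1]
        if tail.isdigit():
            used_numbers.add(int(tail))
    k = 1
    while len(pool) < config.n_families:
        if k not in used_numbers:
            pool.append(f"miR-{k}")
        k += 1
    return pool


def generate_array(config: ArrayConfig) -> tuple[ExpressionMatrix, ArrayTruth]:
    """Generate a probe-level matrix plus the truth behind it.

    Deterministic for a fixed config (single seeded generator, fixed draw
    order): the same config produces bit-identical output.
    """
    if config.n_probes < 50:
        raise ValueError("n_probes must be >= 50")
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if config.noise_floor <= 0:
        raise ValueError("noise_floor must be positive")
    for fam, fold in config.planted_families:
        if abs(fold) < 1:
            raise ValueError(
                f"planted fold for {fam!r} has magnitude {abs(fold)} < 1; "
                "signed folds must satisfy |fold| >= 1"
            )
    if config.n_families < max(1, len(config.planted_families)):
        raise ValueError(
            "n_families is smaller than the number of planted families"
        )
    if not (0.0 <= config.fraction_expressed <= 1.0):
        raise ValueError("fraction_expressed must lie in [0, 1]")

    rng = np.random.default_rng(config.seed)
    nu = float(config.noise_floor)
    cv = float(config.cv_above_floor)
    bsd = float(config.effective_background_sd)
    n = config.n_probes

    families = _family_pool(config)
    species = _species_codes(config.n_species, rng)
    planted_fold = dict(config.planted_families)

    fam_idx = rng.integers(0, len(families), size=n)
    sp_idx = rng.integers(0, len(species), size=n)
    letter_choice = rng.choice(["", "a", "b", "c"], size=n, p=[0.4, 0.2, 0.2, 0.2])
    arm_choice = rng.choice(["", "-5p", "-3p"], size=n, p=[0.5, 0.25, 0.25])
    expressed = rng.random(n) < config.fraction_expressed

    lo_e, hi_e = config.expressed_mean_range
    lo_u, hi_u = config.unexpressed_mean_range
    lo_p, hi_p = config.planted_mean_range
    mean_expressed = nu * np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), size=n))
    mean_unexpressed = nu * np.exp(rng.uniform(np.log(lo_u), np.log(hi_u), size=n))
    mean_planted = nu * np.exp(rng.uniform(np.log(lo_p), np.log(hi_p), size=n))

    fam_names = np.array(families, dtype=object)[fam_idx]
    # guarantee every planted family a minimum membership (uniform
    # assignment can miss a family entirely on small arrays)
    for fam in planted_fold:
        short = config.min_planted_members - int((fam_names == fam).sum())
        if short > 0:
            free = np.flatnonzero(
                ~np.isin(fam_names, list(planted_fold))
            )
            take = rng.choice(free, size=short, replace=False)
            fam_names[take] = fam
    is_planted = np.array([f in planted_fold for f in fam_names])
    expressed = expressed | is_planted

    mean_acr = np.where(expressed, mean_expressed, mean_unexpressed)
    mean_acr = np.where(is_planted, mean_planted, mean_acr)
    folds = np.array([planted_fold.get(f, 1.0) for f in fam_names])
    mean_lh = np.where(
        folds >= 0, mean_acr * np.abs(folds), mean_acr / np.abs(folds)
    )
    mean_lh = np.where(is_planted, mean_lh, mean_acr)

    # unique miRBase-style probe ids
    probe_ids: list[str] = []
    seen: set[str] = set()
    for i in range(n):
        base = f"{species[sp_idx[i]]}-{fam_names[i]}{letter_choice[i]}"
        name = f"{base}{arm_choice[i]}"
        locus = 1
        while name in seen:
            name = f"{base}-{locus}{arm_choice[i]}"
            locus += 1
        seen.add(name)
        probe_ids.append(name)

    g_a, g_b = config.groups
    m = config.n_per_group
    sample_ids = [f"{g_a}_{j + 1}" for j in range(m)] + [
        f"{g_b}_{j + 1}" for j in range(m)
    ]
    group_labels = [g_a] * m + [g_b] * m

    mu = np.column_stack(
        [np.repeat(mean_acr[:, None], m, axis=1), np.repeat(mean_lh[:, None], m, axis=1)]
    )
    sd = np.maximum(bsd, cv * mu)
    intensities = np.maximum(_EPS, rng.normal(mu, sd))

    matrix = ExpressionMatrix(
        values=pd.DataFrame(intensities, index=pd.Index(probe_ids, name="probe_id"),
                            columns=sample_ids),
        groups=pd.Series(group_labels, index=sample_ids, name="group"),
    )
    truth = ArrayTruth(
        noise_floor=nu,
        probe_truth=pd.DataFrame(
            {
                "true_mean_ACR": mean_acr,
                "true_mean_LH": mean_lh,
                "family": fam_names,
                "species": np.array(species, dtype=object)[sp_idx],
                "is_differential": is_planted,
                "planted_fold": folds,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        ),
        design={"n_ACR": m, "n_LH": m, "groups": list(config.groups)},
        seed=config.seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrConfig:
    """Settings for :func:`generate_qpcr`.

    ``true_ratios`` maps each target miRNA to the true test/baseline
    expression ratio recovered by the comparative-Ct method; the reference
    miRNA (miR-103 by default, a stably expressed miRNA) always has ratio 1.
    """

    mirnas: tuple[str, ...]
    true_ratios: dict[str, float] = field(default_factory=dict)
    reference: str = "miR-103"
    groups: tuple[str, str] = ("ACR", "LH")  # (baseline, test)
    n_per_group: int = 6
    ct_noise_sd: float = 0.0
    reference_ct: float = 20.0
    seed: int = 0


def generate_qpcr(config: QpcrConfig) -> pd.DataFrame:
    """Ct table such that 2^-ddCt recovers ``true_ratios`` in expectation.

    Returns a long DataFrame with columns (mirna, sample_id, group, ct).
    """
    if config.reference not in config.mirnas:
        raise ValueError(
            f"reference miRNA {config.reference!r} missing from mirnas list"
        )
    for mir, r in config.true_ratios.items():
        if r <= 0:
            raise ValueError(f"true ratio for {mir!r} must be positive, got {r}")
    rng = np.random.default_rng(config.seed)
    baseline, test = config.groups
    rows = []
    base_ct = {
        mir: (config.reference_ct if mir == config.reference
              else float(rng.uniform(22.0, 28.0)))
        for mir in config.mirnas
    }
    for mir in config.mirnas:
        ratio = 1.0 if mir == config.reference else config.true_ratios.get(mir, 1.0)
        # ratio = 2^-ddCt with the reference flat across groups, so the
        # target's test-group Ct shifts by -log2(ratio) cycles.
        shift = -np.log2(ratio)
        for group, ct0 in ((baseline, base_ct[mir]), (test, base_ct[mir] + shift)):
            if mir == config.reference:
                ct0 = base_ct[mir]
            for j in range(config.n_per_group):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                rows.append(
                    {
                        "mirna": mir,
                        "sample_id": f"{group}_{j + 1}",
                        "group": group,
                        "ct": ct0 + noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# densitometry / viability / reporter tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssayConfig:
    """Settings for :func:`generate_assay_tables`.

    ``densitometry_ratios`` maps group -> true target/actin ratio relative to
    the baseline group; ``viability_fractions`` maps condition -> true
    viability fraction of control; ``reporter_fractions`` maps construct ->
    true firefly/Renilla activity as a fraction of the control construct.
    """

    densitometry_ratios: dict[str, float] = field(
        default_factory=lambda: {"ACR": 1.0, "LH": 2.0}
    )
    baseline_group: str = "ACR"
    lanes_per_group: int = 3
    actin_base: float = 100.0
    band_base_ratio: float = 0.8  # baseline target/actin level

    viability_fractions: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "OGD": 0.35}
    )
    control_condition: str = "control"
    control_corrected: float = 1.2  # control A450 - A690
    a690: float = 0.05
    replicates: int = 3

    reporter_fractions: dict[str, float] = field(
        default_factory=lambda: {"control": 1.0, "UBE2I_miR-182": 0.6}
    )
    control_construct: str = "control"
    control_ratio: float = 2.0  # control firefly/Renilla
    renilla_base: float = 1e5

    noise_cv: float = 0.0
    seed: int = 0


def generate_assay_tables(
    config: AssayConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (densitometry, absorbance, luminescence) tables.

    With ``noise_cv = 0`` the downstream assay arithmetic recovers every
    planted value exactly.
    """
    for g, r in config.densitometry_ratios.items():
        if r <= 0:
            raise ValueError(f"densitometry ratio for {g!r} must be positive")
    for c, f in config.viability_fractions.items():
        a450 = config.a690 + f * config.control_corrected
        if not (0.0 <= a450 <= 4.0):
            raise ValueError(f"absorbance for condition {c!r} out of range [0, 4]")
    for c, f in config.reporter_fractions.items():
        if f < 0:
            raise ValueError(f"reporter fraction for {c!r} must be non-negative")
    if config.baseline_group not in config.densitometry_ratios:
        raise ValueError("baseline group missing from densitometry_ratios")

    rng = np.random.default_rng(config.seed)

    def jitter() -> float:
        return float(np.exp(rng.normal(0.0, config.noise_cv))) if config.noise_cv else 1.0

    dens_rows = []
    for group, ratio in config.densitometry_ratios.items():
        for j in range(config.lanes_per_group):
            actin = config.actin_base * jitter()
            target = config.band_base_ratio * ratio * actin * jitter()
            if target < 0 or actin < 0:
                raise ValueError("negative band intensity generated")
            dens_rows.append(
                {
                    "lane_id": f"{group}_{j + 1}",
                    "group": group,
                    "target_band": target,
                    "actin_band": actin,
                }
            )

    absorb_rows = []
    for cond, frac in config.viability_fractions.items():
        for j in range(config.replicates):
            corrected = frac * config.control_corrected * jitter()
            absorb_rows.append(
                {
                    "well_id": f"{cond}_{j + 1}",
                    "condition": cond,
                    "a450": config.a690 + corrected,
                    "a690": config.a690,
                }
            )

    lum_rows = []
    for construct, frac in config.reporter_fractions.items():
        for j in range(config.replicates):
            renilla = config.renilla_base * jitter()
            firefly = frac * config.control_ratio * renilla * jitter()
            lum_rows.append(
                {
                    "well_id": f"{construct}_{j + 1}",
                    "construct": construct,
                    "firefly": firefly,
                    "renilla": renilla,
                }
            )

    return (
        pd.DataFrame(dens_rows),
        pd.DataFrame(absorb_rows),
        pd.DataFrame(lum_rows),
    )


# ---------------------------------------------------------------------------
# sequence fixtures
# ---------------------------------------------------------------------------

_RNA = np.array(list("ACGU"))
_COMP = {"A": "U", "C": "G", "G": "C", "U": "A"}


def random_mature_mirna(length: int = 22, seed: int = 0) -> str:
    """Random mature miRNA sequence (RNA, 5'->3')."""
    if length < 15:
        raise ValueError("mature miRNA must be at least 15 nt")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(_RNA, size=length))


def target_with_planted_sites(
    mirna: str,
    positions: Sequence[int],
    site_type: str = "8mer",
    length: int = 200,
    seed: int = 0,
) -> str:
    """Random RNA target with canonical seed sites planted at ``positions``.

    Each position is the 0-based start of the 6mer seed-match core. The
    planted site is built from the reverse complement of miRNA positions 2-7,
    extended per ``site_type`` (m8 complement 5' of the core, A opposite
    position 1 just 3' of it).
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(_RNA, size=length))
    mir = mirna.upper().replace("T", "U")
    core = "".join(_COMP[b] for b in reversed(mir[1:7]))
    for pos in positions:
        if pos < 1 or pos + 7 > length:
            raise ValueError("planted site does not fit inside the target")
        seq[pos:pos + 6] = list(core)
        if site_type in ("7mer-m8", "8mer"):
            seq[pos - 1] = _COMP[mir[7]]
        else:
            # ensure no accidental m8 extension
            choices = [b for b in "ACGU" if b != _COMP[mir[7]]]
            seq[pos - 1] = choices[int(rng.integers(len(choices)))]
        if site_type in ("7mer-A1", "8mer"):
            seq[pos + 6] = "A"
        else:
            choices = [b for b in "CGU"]
            seq[pos + 6] = choices[int(rng.integers(3))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# family-table stand-in
# ---------------------------------------------------------------------------


def synthetic_family_table() -> pd.DataFrame:
    """Synthetic stand-in for the study's selected-miRNA list.

    The original supplementary list of fold-selected miRNAs is not
    redistributable, so this constructs, deterministically, a (probe name,
    signed fold) table with the same published summary structure: 405 entries
    grouping by parent-family name into 33 families, the miR-200 family the
    largest with 48 members, all down-regulated with extreme fold -3.04,
    exactly one sign-discordant family (miR-125), and more up- than
    down-regulated families overall. Member names vary species prefixes, arms
    and lettered variants so that the grouping genuinely exercises the name
    parser. This is a synthetic fixture, not the original data.
    """
    species = ["hsa", "mmu", "rno", "cfa", "bta", "gga", "dre", "ptr",
               "mml", "ssc", "oan", "mdo"]
    arms = ["", "-5p", "-3p"]

    def members(family: str, n: int, folds: Sequence[float]) -> list[tuple[str, float]]:
        assert len(folds) == n
        letters = ["", "a", "b", "c", "d", "e", "f"]
        out = []
        for i in range(n):
            sp = species[i % len(species)]
            if family.startswith("let"):
                base, letter = "let-7", letters[1 + i % 6]
            else:
                base, letter = family, letters[i % len(letters)]
            arm = arms[(i // len(species)) % len(arms)]
            name = f"{sp}-{base}{letter}{arm}"
            # disambiguate collisions with a duplicate-locus suffix
            if any(name == nm for nm, _ in out):
                name = f"{sp}-{base}{letter}-{1 + i % 3}{arm}"
            if any(name == nm for nm, _ in out):
                name = f"{sp}-{base}{letter}-{4 + i}{arm}"
            out.append((name, folds[i]))
        return out

    rows: list[tuple[str, float]] = []
    # the dominant down-regulated family: 48 members, extreme -3.04
    down48 = [-(1.30 + 0.03 * i) for i in range(47)] + [-3.04]
    rows += members("miR-200", 48, down48)
    # the single discordant family
    rows += members("miR-125", 6, [-1.5, -1.4, 1.6, -1.3, 1.4, -2.0])

    # 31 further families, each internally concordant; 20 up, 11 down so that
    # up-regulated families are the majority
    other = [
        ("miR-141", 14, -1), ("miR-182", 12, -1), ("miR-183", 12, -1),
        ("miR-96", 10, -1), ("miR-429", 8, -1), ("miR-122", 8, -1),
        ("let-7", 30, 1), ("miR-34", 24, 1), ("miR-206", 18, 1),
        ("miR-30", 22, 1), ("miR-29", 20, 1), ("miR-21", 16, 1),
        ("miR-9", 13, 1), ("miR-124", 12, 1), ("miR-128", 11, 1),
        ("miR-132", 10, 1), ("miR-138", 10, 1), ("miR-103", 9, -1),
        ("miR-107", 9, 1), ("miR-15", 9, 1), ("miR-16", 8, 1),
        ("miR-17", 8, 1), ("miR-19", 8, -1), ("miR-23", 8, 1),
        ("miR-26", 7, 1), ("miR-27", 7, -1), ("miR-99", 7, 1),
        ("miR-100", 6, 1), ("miR-181", 6, -1), ("miR-210", 5, 1),
        ("miR-320", 4, -1),
    ]
    for fam, n, sign in other:
        folds = [sign * (1.26 + 0.05 * (i % 9) + 0.11 * (i // 9)) for i in range(n)]
        rows += members(fam, n, folds)

    df = pd.DataFrame(rows, columns=["probe_id", "fold"])
    assert len(df) == 405, len(df)
    assert not df["probe_id"].duplicated().any()
    return df
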