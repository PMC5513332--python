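"""Genotype state spaces and inheritance rules for each model variant.

Four variants are supported:

``baseline``
    Wild-type population, classes ``M`` (males) and ``F`` (females).
``drive``
    Driving-Y males ``H`` added; no resistance.
``modelI``
    Target-site resistance on the X chromosome: four male classes
    (driving/wild Y × susceptible/resistant X) and three female classes
    (X genotypes SS, SR, RR).  Resistant Xs arise with probability ``u``
    in the X-bearing gametes of driving-Y males only.
``modelII``
    Dominant autosomal suppressor of the nuclease: six male classes
    (driving/wild Y × suppressor genotypes ss/Ss/SS) and three female
    classes.  Mutations arise at birth with probability ``2 v`` per
    newborn (one per autosome copy); a driving Y carried with at least one
    suppressor allele transmits Mendelian 50:50.

All the biology is encoded in a per-variant *birth tensor*
``T[mother, father, child]``: the probability that a single birth from a
given mother class, sired by a given father class, produces each child
class.  Rows sum to 1.  The deterministic right-hand sides, the branching
linearization, and the stochastic simulator all draw on the same tensor,
so the three engines cannot drift apart.

Conventions used throughout: sons inherit the father's Y and the mother's
X; daughters inherit one X from each parent.  A driving Y distorts the
sex ratio (fraction ``m`` sons) only when the father's own X is
susceptible (Model I) and he carries no suppressor allele (Model II);
otherwise transmission is Mendelian.  Father choice is weighted by class
count times male fitness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = ["GenotypeSystem", "VARIANTS"]

VARIANTS = ("baseline", "drive", "modelI", "modelII")


@dataclass(frozen=True)
class GenotypeSystem:
    """Genotype classes, fitnesses and the birth tensor for one variant."""

    variant: str
    classes: tuple[str, ...]
    male_idx: np.ndarray       # indices of male classes within `classes`
    female_idx: np.ndarray     # indices of female classes
    male_fitness: np.ndarray   # fitness multiplier per male class
    female_fitness: np.ndarray
    birth_tensor: np.ndarray   # T[mother, father, child], rows sum to 1
    mutant_copies: np.ndarray  # mutant allele copies carried per class
    drive_male_idx: np.ndarray  # classes counting as driving-Y fathers

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def index(self, label: str) -> int:
        return self.classes.index(label)

    @classmethod
    def build(cls, variant: str, params: ModelParams) -> "GenotypeSystem":
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        builder = {
            "baseline": _build_baseline,
            "drive": _build_drive,
            "modelI": _build_model_i,
            "modelII": _build_model_ii,
        }[variant]
        return builder(params)


def _finalize(variant, classes, males, females, male_fit, female_fit, T,
              copies, drive_males):
    classes = tuple(classes)
    idx = {c: i for i, c in enumerate(classes)}
    T = np.asarray(T, dtype=float)
    row_sums = T.sum(axis=2)
    if not np.allclose(row_sums, 1.0, atol=1e-12):
        raise AssertionError("birth tensor rows must sum to 1")
    return GenotypeSystem(
        variant=variant,
        classes=classes,
        male_idx=np.array([idx[c] for c in males], dtype=int),
        female_idx=np.array([idx[c] for c in females], dtype=int),
        male_fitness=np.asarray(male_fit, dtype=float),
        female_fitness=np.asarray(female_fit, dtype=float),
        birth_tensor=T,
        mutant_copies=np.asarray(copies, dtype=float),
        drive_male_idx=np.array([idx[c] for c in drive_males], dtype=int),
    )


def _build_baseline(params: ModelParams) -> GenotypeSystem:
    classes = ["M", "F"]
    # one mother (F), one father (M): offspring 50:50
    T = np.zeros((1, 1, 2))
    T[0, 0, 0] = 0.5
    T[0, 0, 1] = 0.5
    return _finalize("baseline", classes, ["M"], ["F"], [1.0], [1.0], T,
                     [0.0, 0.0], [])


def _build_drive(params: ModelParams) -> GenotypeSystem:
    m = params.m
    classes = ["H", "M", "F"]
    males, females = ["H", "M"], ["F"]
    T = np.zeros((1, 2, 3))
    # father H: fraction m driving-Y sons, (1-m) daughters
    T[0, 0] = [m, 0.0, 1.0 - m]
    # father M: Mendelian
    T[0, 1] = [0.0, 0.5, 0.5]
    return _finalize("drive", classes, males, females, [1.0, 1.0], [1.0], T,
                     [0.0, 0.0, 0.0], ["H"])


def _build_model_i(params: ModelParams) -> GenotypeSystem:
    m, u, w = params.m, params.u, params.w
    males = ["H", "M", "H_R", "M_R"]
    females = ["F", "F_R", "F_RR"]
    classes = males + females
    idx = {c: i for i, c in enumerate(classes)}

    # maternal X gamete: probability the transmitted X is resistant
    mat_R = {"F": 0.0, "F_R": 0.5, "F_RR": 1.0}
    # father rules: (P(son), son Y type, P(paternal X resistant | daughter))
    # driving Y acts only when the father's own X is susceptible; resistant
    # mutations arise (probability u) only in X gametes of such fathers
    fathers = {
        "H": (m, "drive", u),
        "M": (0.5, "wild", 0.0),
        "H_R": (0.5, "drive", 1.0),
        "M_R": (0.5, "wild", 1.0),
    }
    son_class = {("drive", 0): "H", ("drive", 1): "H_R",
                 ("wild", 0): "M", ("wild", 1): "M_R"}
    daughter_class = {0: "F", 1: "F_R", 2: "F_RR"}

    T = np.zeros((3, 4, 7))
    for fi, mo in enumerate(females):
        qR = mat_R[mo]
        for ai, fa in enumerate(males):
            p_son, y_type, pat_R = fathers[fa]
            for mat_is_R, p_mat in ((0, 1.0 - qR), (1, qR)):
                if p_mat == 0.0:
                    continue
                T[fi, ai, idx[son_class[(y_type, mat_is_R)]]] += p_son * p_mat
                for pat_is_R, p_pat in ((0, 1.0 - pat_R), (1, pat_R)):
                    if p_pat == 0.0:
                        continue
                    child = daughter_class[mat_is_R + pat_is_R]
                    T[fi, ai, idx[child]] += (1.0 - p_son) * p_mat * p_pat

    male_fit = [1.0, 1.0, w * w, w * w]      # hemizygous resistant males: w^2
    female_fit = [1.0, w, w * w]             # F_R: w, F_RR: w^2
    copies = [0.0, 0.0, 1.0, 1.0, 0.0, 1.0, 2.0]
    return _finalize("modelI", classes, males, females, male_fit, female_fit,
                     T, copies, ["H", "H_R"])


def _build_model_ii(params: ModelParams) -> GenotypeSystem:
    m, v, w = params.m, params.v, params.w
    males = ["H", "M", "H_S", "M_S", "H_SS", "M_SS"]
    females = ["F", "F_S", "F_SS"]
    classes = males + females
    idx = {c: i for i, c in enumerate(classes)}

    # suppressor-allele transmission probability by genotype (# S copies)
    geno_S = {"": 0.0, "_S": 0.5, "_SS": 1.0}

    def suffix(label):
        if label.endswith("_SS"):
            return "_SS"
        if label.endswith("_S"):
            return "_S"
        return ""

    geno_suffix = {0: "", 1: "_S", 2: "_SS"}

    T = np.zeros((3, 6, 9))
    for fi, mo in enumerate(females):
        qS = geno_S[suffix(mo)]
        for ai, fa in enumerate(males):
            fa_suffix = suffix(fa)
            pS = geno_S[fa_suffix]
            y_type = "drive" if fa.startswith("H") else "wild"
            # drive acts only for an unsuppressed driving-Y father
            p_son = m if (y_type == "drive" and fa_suffix == "") else 0.5
            for n_mat, p_mat in ((0, 1.0 - qS), (1, qS)):
                for n_pat, p_pat in ((0, 1.0 - pS), (1, pS)):
                    p = p_mat * p_pat
                    if p == 0.0:
                        continue
                    n_copies = n_mat + n_pat
                    # de novo suppressor mutation at birth: ss newborns
                    # become Ss with probability 2v (double mutants ignored)
                    child_dist = {n_copies: 1.0}
                    if n_copies == 0 and v > 0.0:
                        child_dist = {0: 1.0 - 2.0 * v, 1: 2.0 * v}
                    for nc, pc in child_dist.items():
                        g = geno_suffix[nc]
                        son = ("H" if y_type == "drive" else "M") + g
                        T[fi, ai, idx[son]] += p_son * p * pc
                        T[fi, ai, idx["F" + g]] += (1.0 - p_son) * p * pc

    male_fit = [1.0, 1.0, w, w, w * w, w * w]
    female_fit = [1.0, w, w * w]
    copies = [0.0, 0.0, 1.0, 1.0, 2.0, 2.0, 0.0, 1.0, 2.0]
    return _finalize("modelII", classes, males, females, male_fit, female_fit,
                     T, copies, ["H", "H_S", "H_SS"])
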