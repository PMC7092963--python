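"""Trial-plan generation for the dyadic word-by-word paradigm.

One trial is a pair of sentences (13 words in total) read aloud in
alternation by two participants.  The 4th word is a homonym, the 8th
word the critical word (CW) that disambiguates it.  Before the sentence
each participant silently reads a prime that fixes one homonym meaning,
so the CW is expected (congruent) or unexpected (incongruent) per
participant.  Because the CW sits at an even position it is always
spoken by the participant who did *not* start the sentence; the starter
perceives it.

The default design reproduces the published study's counts exactly:
240 trials, 75% congruent / 25% incongruent per participant, each
participant starting (and therefore perceiving the CW in) half of the
trials, with each participant's incongruent trials split 2:1 between
perceived-CW and spoken-CW roles (40 vs 20 per 240 trials).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

P1, P2 = 1, 2
PARTICIPANTS = (P1, P2)

HOMONYM_INDEX = 4  # 1-based word position of the homonym
CW_INDEX = 8       # 1-based word position of the critical word
N_WORDS = 13

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"


class InfeasibleDesignError(ValueError):
    """The requested design counts cannot be realized with whole trials."""


@dataclass(frozen=True)
class SentenceTemplate:
    """One trial's sentence material (13 words, two primes)."""

    sentence_id: str
    words: tuple[str, ...]
    prime_a: str  # congruent with the used CW
    prime_b: str  # incongruent with the used CW
    homonym_index: int = HOMONYM_INDEX
    cw_index: int = CW_INDEX

    def __post_init__(self):
        if len(self.words) != N_WORDS:
            raise ValueError(
                f"{self.sentence_id}: expected {N_WORDS} words, got {len(self.words)}"
            )
        if self.homonym_index != HOMONYM_INDEX or self.cw_index != CW_INDEX:
            raise ValueError("homonym must be word 4 and the critical word word 8")
        if self.prime_a == self.prime_b:
            raise ValueError("primes must differ")

    @property
    def word_lengths(self) -> tuple[int, ...]:
        return tuple(len(w) for w in self.words)


@dataclass(frozen=True)
class DesignSpec:
    """Session-level design counts.

    ``incongruent_split`` is the per-participant allocation of
    incongruent trials to (perceived-CW, spoken-CW) roles and must sum
    to ``frac_incongruent_per_participant * n_trials``.
    """

    n_trials: int = 240
    frac_incongruent_per_participant: float = 0.25
    frac_starter_p1: float = 0.5
    incongruent_split: tuple[int, int] | None = None  # (perceiving, speaking)

    def resolved_split(self) -> tuple[int, int]:
        n_inc = self.frac_incongruent_per_participant * self.n_trials
        if abs(n_inc - round(n_inc)) > 1e-9:
            raise InfeasibleDesignError(
                f"frac_incongruent_per_participant x n_trials = {n_inc} is not an integer"
            )
        n_inc = int(round(n_inc))
        if self.incongruent_split is None:
            # default 2:1 perceived:spoken split
            if n_inc % 3:
                raise InfeasibleDesignError(
                    f"default 2:1 incongruent split needs a multiple of 3, got {n_inc}"
                )
            return (2 * n_inc // 3, n_inc // 3)
        a, b = self.incongruent_split
        if a < 0 or b < 0 or a + b != n_inc:
            raise InfeasibleDesignError(
                f"incongruent_split {self.incongruent_split} must sum to {n_inc}"
            )
        return (int(a), int(b))


@dataclass(frozen=True)
class Trial:
    trial_index: int
    sentence: SentenceTemplate
    starter: int  # participant speaking odd word positions 1,3,...,13
    congruency: dict = field(compare=False)  # participant -> label

    @property
    def cw_speaker(self) -> int:
        # word 8 is even, spoken by the non-starter
        return P2 if self.starter == P1 else P1

    @property
    def cw_perceiver(self) -> int:
        return self.starter

    def speaker_of(self, word_position: int) -> int:
        """Participant who reads aloud the given 1-based word position."""
        if word_position % 2 == 1:
            return self.starter
        return P2 if self.starter == P1 else P1

    def prime_for(self, participant: int) -> str:
        if self.congruency[participant] == CONGRUENT:
            return self.sentence.prime_a
        return self.sentence.prime_b


@dataclass(frozen=True)
class PlanCounts:
    """Per-participant tallies, recomputable from the trial list."""

    total: dict
    congruent: dict
    incongruent: dict
    producer_of_cw: dict
    perceiver_of_cw: dict
    incongruent_while_perceiving: dict
    incongruent_while_speaking: dict


@dataclass(frozen=True)
class TrialPlan:
    trials: tuple[Trial, ...]
    spec: DesignSpec

    @property
    def counts(self) -> PlanCounts:
        return plan_counts(self)

    def __len__(self) -> int:
        return len(self.trials)


def plan_counts(plan: TrialPlan) -> PlanCounts:
    """Tally the per-participant design counts of a plan (pure function)."""
    z = {p: 0 for p in PARTICIPANTS}

    def tally(pred):
        out = dict(z)
        for t in plan.trials:
            for p in PARTICIPANTS:
                out[p] += int(pred(t, p))
        return out

    return PlanCounts(
        total=tally(lambda t, p: True),
        congruent=tally(lambda t, p: t.congruency[p] == CONGRUENT),
        incongruent=tally(lambda t, p: t.congruency[p] == INCONGRUENT),
        producer_of_cw=tally(lambda t, p: t.cw_speaker == p),
        perceiver_of_cw=tally(lambda t, p: t.cw_perceiver == p),
        incongruent_while_perceiving=tally(
            lambda t, p: t.congruency[p] == INCONGRUENT and t.cw_perceiver == p
        ),
        incongruent_while_speaking=tally(
            lambda t, p: t.congruency[p] == INCONGRUENT and t.cw_speaker == p
        ),
    )


def _category_counts(spec: DesignSpec) -> dict[str, int]:
    """Decompose the spec into whole-trial category counts.

    Categories: ``inc_perc_p`` = incongruent for participant p while p
    perceives the CW (p starts); ``inc_spk_p`` = incongruent for p while
    p speaks the CW (the other starts); ``cong_p1``/``cong_p2`` =
    congruent for both, started by p1/p2.
    """
    n = spec.n_trials
    if n % 2:
        raise InfeasibleDesignError(f"n_trials = {n} must be even")
    if not (0.0 <= spec.frac_incongruent_per_participant <= 1.0):
        raise InfeasibleDesignError("frac_incongruent_per_participant outside [0, 1]")
    a, b = spec.resolved_split()  # per participant: perceiving, speaking
    s1 = spec.frac_starter_p1 * n
    if abs(s1 - round(s1)) > 1e-9:
        raise InfeasibleDesignError(
            f"frac_starter_p1 x n_trials = {s1} is not an integer"
        )
    s1 = int(round(s1))
    n_cong = n - 2 * (a + b)
    if n_cong < 0:
        raise InfeasibleDesignError(
            "incongruent trials exceed n_trials (at most one participant may be "
            "incongruent per trial)"
        )
    # p1 starts in: inc_perc_p1 (a) + inc_spk_p2 (b) + cong_p1
    cong_p1 = s1 - a - b
    cong_p2 = n_cong - cong_p1
    if cong_p1 < 0 or cong_p2 < 0:
        raise InfeasibleDesignError(
            f"starter fraction {spec.frac_starter_p1} incompatible with the "
            f"incongruent split {(a, b)}"
        )
    return {
        "inc_perc_p1": a, "inc_spk_p1": b,
        "inc_perc_p2": a, "inc_spk_p2": b,
        "cong_p1": cong_p1, "cong_p2": cong_p2,
    }


def build_trial_plan(
    spec: DesignSpec,
    sentences: list[SentenceTemplate],
    seed: int,
) -> TrialPlan:
    """Generate a randomized trial plan satisfying ``spec`` exactly.

    Sentences are assigned without replacement; trial order and the
    sentence-to-category assignment are seeded shuffles, so the result
    is deterministic for a fixed ``(spec, sentences, seed)``.
    """
    cats = _category_counts(spec)
    n = spec.n_trials
    if len(sentences) < n:
        raise ValueError(f"need at least {n} sentences, got {len(sentences)}")
    ids = [s.sentence_id for s in sentences]
    if len(set(ids)) != len(ids):
        raise ValueError("sentence_ids must be unique")

    rng = np.random.default_rng(int(seed))
    sent_order = list(rng.permutation(len(sentences))[:n])

    slots: list[str] = []
    for cat in sorted(cats):
        slots.extend([cat] * cats[cat])
    slots = [slots[i] for i in rng.permutation(n)]

    trials = []
    for idx, (cat, si) in enumerate(zip(slots, sent_order)):
        if cat in ("inc_perc_p1", "cong_p1", "inc_spk_p2"):
            starter = P1
        else:
            starter = P2
        congr = {P1: CONGRUENT, P2: CONGRUENT}
        if cat.startswith("inc_"):
            congr[P1 if cat.endswith("p1") else P2] = INCONGRUENT
        trials.append(
            Trial(
                trial_index=idx,
                sentence=sentences[int(si)],
                starter=starter,
                congruency=congr,
            )
        )
    return TrialPlan(trials=tuple(trials), spec=spec)


def validate_plan(plan: TrialPlan, spec: DesignSpec | None = None) -> list[str]:
    """Check all plan invariants; return a list of violations (empty = valid)."""
    spec = spec or plan.spec
    violations: list[str] = []
    seen_sentences: set[str] = set()
    for t in plan.trials:
        if sum(t.congruency[p] == INCONGRUENT for p in PARTICIPANTS) > 1:
            violations.append(
                f"trial {t.trial_index}: incongruent for both participants"
            )
        if t.cw_speaker == t.starter:
            violations.append(f"trial {t.trial_index}: cw_speaker equals starter")
        if t.sentence.sentence_id in seen_sentences:
            violations.append(
                f"trial {t.trial_index}: sentence {t.sentence.sentence_id} reused"
            )
        seen_sentences.add(t.sentence.sentence_id)

    try:
        cats = _category_counts(spec)
    except InfeasibleDesignError as e:
        return violations + [f"spec infeasible: {e}"]

    counts = plan_counts(plan)
    a, b = spec.resolved_split()
    n = spec.n_trials
    expected = {
        "total": {P1: n, P2: n},
        "incongruent": {P1: a + b, P2: a + b},
        "congruent": {P1: n - a - b, P2: n - a - b},
        "incongruent_while_perceiving": {P1: a, P2: a},
        "incongruent_while_speaking": {P1: b, P2: b},
        "perceiver_of_cw": {
            P1: cats["inc_perc_p1"] + cats["inc_spk_p2"] + cats["cong_p1"],
            P2: cats["inc_perc_p2"] + cats["inc_spk_p1"] + cats["cong_p2"],
        },
    }
    expected["producer_of_cw"] = {
        P1: n - expected["perceiver_of_cw"][P1],
        P2: n - expected["perceiver_of_cw"][P2],
    }
    if len(plan.trials) != n:
        violations.append(f"plan has {len(plan.trials)} trials, spec wants {n}")
    for name, exp in expected.items():
        got = getattr(counts, name)
        for p in PARTICIPANTS:
            if got[p] != exp[p]:
                violations.append(
                    f"count {name}[p{p}] = {got[p]}, expected {exp[p]}"
                )
    return violations


def shuffle_plan(plan: TrialPlan, seed: int) -> TrialPlan:
    """Reorder trials of an existing plan (counts are order-invariant)."""
    rng = np.random.default_rng(int(seed))
    perm = rng.permutation(len(plan.trials))
    trials = tuple(
        replace(plan.trials[int(i)], trial_index=k) for k, i in enumerate(perm)
    )
    return TrialPlan(trials=trials, spec=plan.spec)
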