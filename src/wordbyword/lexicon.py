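"""Fixture lexicon of homonym sentence templates.

Each template is one trial's material: 13 words forming two sentences,
with the homonym at position 4 and the critical word (CW) at position 8.
Two primes accompany each template: ``prime_a`` fixes the homonym meaning
the used CW fits (congruent), ``prime_b`` fixes the other meaning
(incongruent).  Two genuine German example templates are included; the
remaining templates are structure-matched placeholders generated
programmatically (pseudo-words with realistic letter counts), since no
full stimulus list is published for this paradigm.
"""

from __future__ import annotations

import numpy as np

from .trial_design import SentenceTemplate

# the two worked German examples (piano/wing, bench/bank)
EXAMPLE_TEMPLATES = [
    SentenceTemplate(
        sentence_id="ex_fluegel",
        words=(
            "Jana", "sieht", "den", "Fluegel",
            "Sie", "beruehrt", "eine", "Taste",
            "und", "hoert", "den", "reinen", "Klang",
        ),
        prime_a="Konzert",
        prime_b="Engel",
    ),
    SentenceTemplate(
        sentence_id="ex_bank",
        words=(
            "Peter", "sucht", "eine", "Bank",
            "Er", "braucht", "etwas", "Ruhe",
            "um", "spaeter", "ausgehen", "zu", "koennen",
        ),
        prime_a="Park",
        prime_b="Kredit",
    ),
]

# syllable pool for pronounceable placeholder words
_SYLLABLES = [
    "ba", "de", "fi", "go", "hu", "ka", "le", "mi", "no", "pu",
    "ra", "se", "ti", "vo", "wa", "zen", "lor", "mak", "tur", "bel",
]

# target letter-count profile per word position (loosely matching the
# name-verb-det-homonym / pronoun-verb-det-noun + subordinate structure)
_POSITION_LENGTHS = (4, 5, 3, 6, 3, 6, 4, 5, 3, 5, 7, 3, 6)


def _make_word(rng: np.random.Generator, n_letters: int) -> str:
    word = ""
    while len(word) < n_letters:
        word += _SYLLABLES[rng.integers(len(_SYLLABLES))]
    return word[:n_letters]


def make_placeholder_template(sentence_id: str, rng: np.random.Generator) -> SentenceTemplate:
    """One structure-matched placeholder trial template."""
    words = []
    for target in _POSITION_LENGTHS:
        n = max(2, int(target + rng.integers(-1, 2)))
        words.append(_make_word(rng, n))
    prime_a = _make_word(rng, int(rng.integers(4, 8)))
    prime_b = _make_word(rng, int(rng.integers(4, 8)))
    while prime_b == prime_a:
        prime_b = _make_word(rng, int(rng.integers(4, 8)))
    return SentenceTemplate(
        sentence_id=sentence_id, words=tuple(words),
        prime_a=prime_a, prime_b=prime_b,
    )


def default_lexicon(n_sentences: int = 240, seed: int = 0) -> list[SentenceTemplate]:
    """The built-in lexicon: the worked examples plus placeholders.

    Deterministic for a fixed seed; ``n_sentences`` distinct templates.
    """
    rng = np.random.default_rng(seed)
    templates = list(EXAMPLE_TEMPLATES[: min(2, n_sentences)])
    i = 0
    while len(templates) < n_sentences:
        templates.append(make_placeholder_template(f"gen_{i:04d}", rng))
        i += 1
    return templates
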