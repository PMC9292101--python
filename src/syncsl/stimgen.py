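"""Pseudo-language stimulus generation.

Builds the artificial lexicons and continuous syllable streams used in
statistical word-form learning experiments: 12 unique consonant-vowel
syllables combine into 4 trisyllabic pseudo-words, which are concatenated
without gaps at 4.5 syllables/s into 2-minute learning streams with an
equal number of non-consecutive repetitions per word.  Part-word foils
(final syllable of one word + first two syllables of another) and the
8-trial two-alternative forced-choice test sets are derived from the
lexicon.  A separate random syllable stream (disjoint inventory, no
consecutive repeats) serves as stimulus for the spontaneous speech
synchronization test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PHONEME_DURATION_MS = 111.0
SYLLABLE_DURATION_MS = 2 * PHONEME_DURATION_MS
DEFAULT_RATE_HZ = 4.5
WORDS_PER_LANGUAGE = 4
SYLLABLES_PER_WORD = 3

# 60 plain-ASCII CV syllables: 12 per learning language (4 languages) plus a
# disjoint pool reserved for the synchronization-test stream.
_CONSONANTS = "bdfgkmnprstv"
_VOWELS = "aeiou"
SYLLABLE_INVENTORY = tuple(
    c + v for v in _VOWELS for c in _CONSONANTS
)  # 60 CV combinations


@dataclass(frozen=True)
class Syllable:
    """A consonant-vowel syllable with fixed phoneme timing."""

    consonant: str
    vowel: str
    duration_ms: float = SYLLABLE_DURATION_MS

    @property
    def symbol(self) -> str:
        return self.consonant + self.vowel

    def __post_init__(self) -> None:
        if self.duration_ms != 2 * PHONEME_DURATION_MS:
            raise ValueError("syllable duration must equal two phoneme durations")


def _syllable(symbol: str) -> Syllable:
    return Syllable(consonant=symbol[:-1], vowel=symbol[-1])


@dataclass(frozen=True)
class PseudoLanguage:
    """12 distinct syllables arranged into 4 trisyllabic words.

    ``words`` holds indices into ``syllables``; each of the 12 syllables is
    used in exactly one word slot, so no syllable repeats across words.
    """

    syllables: tuple[Syllable, ...]
    words: tuple[tuple[int, int, int], ...]
    language_id: str = "L1"

    def __post_init__(self) -> None:
        if len(self.syllables) != 12:
            raise ValueError("a pseudo-language needs exactly 12 syllables")
        if len({s.symbol for s in self.syllables}) != 12:
            raise ValueError("syllables must be distinct")
        if len(self.words) != WORDS_PER_LANGUAGE:
            raise ValueError("a pseudo-language needs exactly 4 words")
        used = [i for w in self.words for i in w]
        if sorted(used) != list(range(12)):
            raise ValueError("the 12 word slots must use each syllable exactly once")

    def word_symbols(self, word_index: int) -> tuple[str, str, str]:
        return tuple(self.syllables[i].symbol for i in self.words[word_index])


@dataclass(frozen=True)
class SpeechStream:
    """A gapless isochronous syllable stream.

    ``tokens`` are word indices for learning streams or syllable indices for
    random (synchronization-test) streams; ``syllable_symbols`` is the fully
    unrolled per-syllable sequence aligned with ``onset_times_s``.
    """

    tokens: tuple[int, ...]
    syllable_symbols: tuple[str, ...]
    onset_times_s: np.ndarray
    rate_hz: float
    duration_s: float
    kind: str = "learning"  # "learning" | "sss"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times_s, float)
        if len(onsets) != len(self.syllable_symbols):
            raise ValueError("one onset per syllable required")
        if len(onsets) > 1:
            gaps = np.diff(onsets)
            if not np.allclose(gaps, 1.0 / self.rate_hz, rtol=0, atol=1e-9):
                raise ValueError("onsets must be isochronous at 1/rate")


@dataclass(frozen=True)
class PartWord:
    """Foil item: final syllable of one word followed by the first two of another."""

    syllables: tuple[str, str, str]
    source_final_word: int
    source_initial_word: int

    def __post_init__(self) -> None:
        if self.source_final_word == self.source_initial_word:
            raise ValueError("part-word sources must be two different words")


@dataclass(frozen=True)
class TestSet:
    """Eight 2AFC trials pairing each word twice against selected part-words."""

    trials: tuple[dict, ...]
    language_id: str = "L1"

    def __post_init__(self) -> None:
        if len(self.trials) != 8:
            raise ValueError("a test set holds exactly 8 trials")


def build_language(
    syllable_pool: list[Syllable | str], seed: int, language_id: str = "L1"
) -> PseudoLanguage:
    """Draw 12 syllables from the pool and arrange them into 4 words.

    Deterministic for a given ``seed``.  Raises ``ValueError`` if the pool has
    fewer than 12 distinct syllables.
    """
    pool = [_syllable(s) if isinstance(s, str) else s for s in syllable_pool]
    symbols = list(dict.fromkeys(s.symbol for s in pool))
    if len(symbols) < 12:
        raise ValueError(
            f"syllable pool has only {len(symbols)} distinct syllables; 12 required"
        )
    rng = np.random.default_rng(seed)
    chosen = [symbols[i] for i in rng.choice(len(symbols), size=12, replace=False)]
    order = rng.permutation(12)
    words = tuple(
        tuple(int(order[3 * w + k]) for k in range(3)) for w in range(4)
    )
    return PseudoLanguage(
        syllables=tuple(_syllable(s) for s in chosen),
        words=words,
        language_id=language_id,
    )


def _balanced_nonadjacent_sequence(
    n_items: int, reps: int, rng: np.random.Generator, max_tries: int = 10_000
) -> list[int]:
    """Uniform item counts, no two adjacent equal.

    Repeated seeded shuffles with rejection; after ``max_tries`` failures the
    last candidate is repaired deterministically by local swaps (always
    possible when reps*(n_items-1) >= reps-ish; guaranteed here for n>=2).
    """
    base = np.repeat(np.arange(n_items), reps)
    seq = None
    for _ in range(max_tries):
        cand = rng.permutation(base)
        if not np.any(cand[1:] == cand[:-1]):
            return cand.tolist()
        seq = cand
    # deterministic repair: for each adjacent duplicate, swap the second
    # element with the first later position where the swap breaks no constraint
    seq = list(seq)
    n = len(seq)
    for i in range(1, n):
        if seq[i] != seq[i - 1]:
            continue
        for j in range(n):
            if seq[j] == seq[i]:
                continue
            left_ok = j == 0 or seq[j - 1] != seq[i]
            right_ok = j == n - 1 or seq[j + 1] != seq[i]
            here_ok = seq[j] != seq[i - 1] and (i == n - 1 or seq[j] != seq[i + 1])
            if left_ok and right_ok and here_ok:
                seq[i], seq[j] = seq[j], seq[i]
                break
    if any(seq[i] == seq[i - 1] for i in range(1, len(seq))):
        raise RuntimeError("could not construct balanced nonadjacent sequence")
    return seq


def generate_stream(
    language: PseudoLanguage,
    duration_s: float = 120.0,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
) -> SpeechStream:
    """Concatenate words in pseudorandom order into a gapless stream.

    Word-token counts are exactly equal and no word immediately repeats.
    If ``duration_s * rate_hz`` does not yield a word count divisible by 4,
    the token count is rounded down to the nearest feasible value and the
    actual duration recorded on the stream.
    """
    n_syll = int(np.floor(duration_s * rate_hz + 1e-9))
    n_words = (n_syll // SYLLABLES_PER_WORD // WORDS_PER_LANGUAGE) * WORDS_PER_LANGUAGE
    if n_words < 8:
        raise ValueError(
            "stream too short: need at least 8 word tokens for balanced "
            "nonadjacent ordering"
        )
    rng = np.random.default_rng(seed)
    tokens = _balanced_nonadjacent_sequence(
        WORDS_PER_LANGUAGE, n_words // WORDS_PER_LANGUAGE, rng
    )
    symbols: list[str] = []
    for t in tokens:
        symbols.extend(language.word_symbols(t))
    onsets = np.arange(len(symbols)) / rate_hz
    return SpeechStream(
        tokens=tuple(tokens),
        syllable_symbols=tuple(symbols),
        onset_times_s=onsets,
        rate_hz=rate_hz,
        duration_s=len(symbols) / rate_hz,
        kind="learning",
    )


def make_part_words(language: PseudoLanguage) -> list[PartWord]:
    """Enumerate all admissible part-words (final syllable x other word): 12."""
    out: list[PartWord] = []
    for wf in range(WORDS_PER_LANGUAGE):
        final_syll = language.word_symbols(wf)[2]
        for wi in range(WORDS_PER_LANGUAGE):
            if wi == wf:
                continue
            first_two = language.word_symbols(wi)[:2]
            out.append(
                PartWord(
                    syllables=(final_syll, first_two[0], first_two[1]),
                    source_final_word=wf,
                    source_initial_word=wi,
                )
            )
    # each syllable is used once per language, so a part-word can never spell
    # an actual word; assert as a guard
    words = {language.word_symbols(w) for w in range(WORDS_PER_LANGUAGE)}
    assert all(pw.syllables not in words for pw in out)
    return out


def build_test_set(language: PseudoLanguage, seed: int) -> TestSet:
    """Assemble the 8-trial 2AFC test.

    Four part-words are drawn from the pool of 12; each word and each selected
    part-word appears exactly twice, in non-repeating (word, part-word) pairs.
    Screen side and auditory order of the word are counterbalanced by a seeded
    fair coin.
    """
    rng = np.random.default_rng(seed)
    pool = make_part_words(language)
    chosen = [pool[i] for i in rng.choice(len(pool), size=4, replace=False)]
    # pair words (0..3, twice each) with part-words (0..3, twice each) such
    # that no (word, part-word) pair repeats: use two random derangement-free
    # pairings: word w meets part-words p1[w] and p2[w] with p1[w] != p2[w]
    while True:
        p1 = rng.permutation(4)
        p2 = rng.permutation(4)
        if np.all(p1 != p2):
            break
    trials = []
    for w in range(4):
        for p in (int(p1[w]), int(p2[w])):
            trials.append(
                {
                    "word": w,
                    "word_syllables": language.word_symbols(w),
                    "part_word": p,
                    "part_word_syllables": chosen[p].syllables,
                    "word_side": "left" if rng.random() < 0.5 else "right",
                    "word_first": bool(rng.random() < 0.5),
                }
            )
    order = rng.permutation(8)
    trials = tuple(trials[i] for i in order)
    return TestSet(trials=trials, language_id=language.language_id)


def generate_sss_stream(
    syllable_pool: list[Syllable | str],
    duration_s: float = 60.0,
    rate_hz: float = DEFAULT_RATE_HZ,
    seed: int = 0,
) -> SpeechStream:
    """Random syllable stream for the synchronization test.

    Twelve syllables (disjoint from the learning languages, by caller
    convention), no pauses, no consecutive repetitions, constant 4.5 Hz.
    """
    pool = [_syllable(s) if isinstance(s, str) else s for s in syllable_pool]
    if len({s.symbol for s in pool}) != 12:
        raise ValueError("synchronization-test pool must hold exactly 12 distinct syllables")
    n = int(np.floor(duration_s * rate_hz + 1e-9))
    rng = np.random.default_rng(seed)
    tokens = [int(rng.integers(12))]
    while len(tokens) < n:
        nxt = int(rng.integers(11))
        if nxt >= tokens[-1]:
            nxt += 1  # uniform over the 11 syllables != previous
        tokens.append(nxt)
    symbols = tuple(pool[t].symbol for t in tokens)
    onsets = np.arange(n) / rate_hz
    return SpeechStream(
        tokens=tuple(tokens),
        syllable_symbols=symbols,
        onset_times_s=onsets,
        rate_hz=rate_hz,
        duration_s=n / rate_hz,
        kind="sss",
    )


def default_language_pools() -> dict[str, tuple[str, ...]]:
    """Partition the 60-syllable inventory: 12 per learning language L1-L4 plus
    a disjoint 12-syllable pool for the synchronization-test stream."""
    inv = SYLLABLE_INVENTORY
    return {
        "L1": inv[0:12],
        "L2": inv[12:24],
        "L3": inv[24:36],
        "L4": inv[36:48],
        "SSS": inv[48:60],
    }


# ---------------------------------------------------------------------------
# I/O: one CSV row per syllable token, JSON manifest per language


def stream_to_frame(stream: SpeechStream) -> pd.DataFrame:
    reps = SYLLABLES_PER_WORD if stream.kind == "learning" else 1
    token_col = np.repeat(stream.tokens, reps)
    return pd.DataFrame(
        {
            "index": np.arange(len(stream.syllable_symbols)),
            "token": token_col,
            "symbol": list(stream.syllable_symbols),
            "onset_s": np.asarray(stream.onset_times_s),
        }
    )


def write_stream_csv(stream: SpeechStream, path: str | Path) -> None:
    stream_to_frame(stream).to_csv(path, index=False)


def read_stream_csv(path: str | Path, rate_hz: float = DEFAULT_RATE_HZ,
                    kind: str = "learning") -> SpeechStream:
    df = pd.read_csv(path)
    reps = SYLLABLES_PER_WORD if kind == "learning" else 1
    tokens = tuple(int(t) for t in df["token"].to_numpy()[::reps])
    return SpeechStream(
        tokens=tokens,
        syllable_symbols=tuple(df["symbol"]),
        onset_times_s=df["onset_s"].to_numpy(),
        rate_hz=rate_hz,
        duration_s=len(df) / rate_hz,
        kind=kind,
    )


def write_language_manifest(language: PseudoLanguage, path: str | Path) -> None:
    manifest = {
        "language_id": language.language_id,
        "syllables": [s.symbol for s in language.syllables],
        "words": [list(w) for w in language.words],
        "phoneme_duration_ms": PHONEME_DURATION_MS,
        "syllable_duration_ms": SYLLABLE_DURATION_MS,
    }
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_language_manifest(path: str | Path) -> PseudoLanguage:
    m = json.loads(Path(path).read_text())
    return PseudoLanguage(
        syllables=tuple(_syllable(s) for s in m["syllables"]),
        words=tuple(tuple(w) for w in m["words"]),
        language_id=m["language_id"],
    )
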