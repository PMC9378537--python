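"""Frozen word lists shared by the syllable counter and the generators.

``REFERENCE_SYLLABLES`` is a fixed 200-word English list with syllable
counts taken from a standard pronunciation dictionary (number of vowel
phones in the primary pronunciation). It serves as the independent
reference the heuristic counter is validated against; the counts are
frozen, not produced by the heuristic.

``LEXICON`` is a 100-word subset (words where heuristic and dictionary
agree) used by the synthetic transcript generator so that generated
reference/hypothesis pairs have known, stable syllable totals.
"""

from __future__ import annotations

__all__ = ["REFERENCE_SYLLABLES", "LEXICON"]

#: word -> dictionary syllable count (frozen reference, 200 entries)
REFERENCE_SYLLABLES: dict[str, int] = {
    # one syllable
    "the": 1, "cat": 1, "sat": 1, "dog": 1, "run": 1, "jump": 1,
    "house": 1, "mouse": 1, "time": 1, "make": 1, "like": 1, "word": 1,
    "world": 1, "speech": 1, "sound": 1, "voice": 1, "phone": 1, "test": 1,
    "green": 1, "through": 1, "school": 1, "friend": 1, "night": 1, "light": 1, "white": 1,
    "black": 1, "blue": 1, "red": 1, "one": 1, "two": 1, "three": 1,
    "five": 1, "nine": 1, "ten": 1, "big": 1, "small": 1, "fast": 1,
    "slow": 1, "loud": 1, "soft": 1, "clear": 1, "noise": 1, "tone": 1,
    "pitch": 1, "track": 1, "count": 1, "rate": 1, "scale": 1, "fit": 1,
    "line": 1, "slope": 1, "mean": 1, "point": 1, "group": 1, "queue": 1,
    # two syllables
    "table": 2, "little": 2, "apple": 2, "people": 2, "paper": 2,
    "water": 2, "over": 2, "under": 2, "after": 2, "before": 2,
    "better": 2, "matter": 2, "number": 2, "letter": 2, "other": 2,
    "mother": 2, "father": 2, "sister": 2, "doctor": 2,
    "patient": 2, "record": 2, "signal": 2, "student": 2, "teacher": 2,
    "window": 2, "open": 2, "happy": 2, "very": 2, "many": 2, "money": 2,
    "story": 2, "study": 2, "early": 2, "body": 2, "city": 2, "party": 2,
    "never": 2, "always": 2, "often": 2, "again": 2, "around": 2,
    "about": 2, "above": 2, "across": 2, "because": 2, "between": 2,
    "machine": 2, "measure": 2, "picture": 2, "question": 2, "reason": 2, "science": 2, "business": 2, "being": 2,
    "quiet": 2, "poem": 2, "create": 2, "diet": 2, "lion": 2,
    "wednesday": 2, "colonel": 2, "chocolate": 2, "evening": 2,
    "camera": 2, "different": 2, "several": 2, "listen": 2, "missing": 2,
    # three syllables
    "syllable": 3, "computer": 3, "important": 3, "hospital": 3,
    "telephone": 3, "understand": 3, "remember": 3, "together": 3,
    "tomorrow": 3, "yesterday": 3, "animal": 3, "family": 3, "energy": 3,
    "example": 3, "exercise": 3, "general": 3, "history": 3, "holiday": 3,
    "however": 3, "imagine": 3, "industry": 3, "library": 3, "medical": 3,
    "memory": 3, "minister": 3, "multiply": 3, "musical": 3, "natural": 3,
    "numeral": 3, "opposite": 3, "personal": 3, "physical": 3,
    "position": 3, "possible": 3, "practical": 3, "president": 3,
    "probably": 3, "quality": 3, "quantity": 3, "recognize": 3,
    "regular": 3, "seventy": 3, "similar": 3, "terrible": 3, "united": 3,
    "vitamin": 3, "wonderful": 3, "idea": 3, "area": 3, "interesting": 3,
    "period": 3, "radio": 3, "basically": 3,
    # four syllables
    "information": 4, "education": 4, "american": 4, "community": 4,
    "necessary": 4, "ordinary": 4, "television": 4, "population": 4,
    "particular": 4, "impossible": 4, "experience": 4, "original": 4,
    "security": 4, "activity": 4, "identify": 4, "emergency": 4,
    "calculator": 4, "operation": 4, "material": 4, "estimation": 4,
    # five syllables
    "university": 5, "opportunity": 5, "examination": 5, "organization": 5,
}

#: 100-word generator lexicon: word -> syllable count (heuristic-consistent
#: subset of the reference list)
LEXICON: dict[str, int] = {
    w: REFERENCE_SYLLABLES[w]
    for w in (
        "the", "cat", "sat", "dog", "run", "jump", "house", "mouse",
        "time", "make", "like", "word", "world", "speech", "sound",
        "voice", "phone", "test", "green", "through", "school", "friend",
        "night", "light", "white", "black", "blue", "red", "one", "two",
        "three", "five", "nine", "ten", "big", "small", "fast", "slow",
        "loud", "soft", "clear", "noise", "tone", "pitch", "track",
        "count", "rate", "scale", "fit", "line", "slope", "mean", "point",
        "group", "table", "little", "apple", "people", "paper", "water",
        "over", "under", "after", "before", "better", "matter", "number",
        "letter", "other", "mother", "father", "sister", "doctor",
        "record", "signal", "student", "teacher", "window", "open",
        "happy", "very", "many", "money", "story", "study", "early",
        "body", "city", "party", "never", "always", "often", "again",
        "computer", "hospital", "telephone", "remember", "together",
        "family", "information",
    )
}
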