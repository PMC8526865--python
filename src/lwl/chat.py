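"""Minimal CHAT (.cha) transcript writing and reading.

CHAT is the transcript format of the CHILDES child-language corpora: header
lines start with ``@`` (``@Participants``, ``@ID`` with the child's age as
``years;months.days``), utterances with ``*SPK:<TAB>``, dependent tiers with
``%``.  Only the small subset needed for word-token counting is handled:
speaker codes, the target child's age, and plain utterance tokens
(continuation lines and dependent tiers are folded in / ignored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

_PUNCT = re.compile(r"^[.!?,;:+/\"'«»„“”()\[\]<>-]+$")
_STRIP = re.compile(r"[.,!?;:\"“”]+$")


class ChatError(ValueError):
    """Document cannot be interpreted as CHAT."""


def format_age(months: float) -> str:
    """Months -> CHAT ``y;mm.dd`` age string (30-day months)."""
    if months < 0:
        raise ChatError(f"invalid child age: {months} months")
    years = int(months // 12)
    rem = months - 12 * years
    mm = int(rem)
    dd = int(round((rem - mm) * 30))
    if dd == 30:
        mm, dd = mm + 1, 0
        if mm == 12:
            years, mm = years + 1, 0
    return f"{years};{mm:02d}.{dd:02d}"


def parse_age(age: str) -> "float | None":
    """CHAT age string -> months, or None if absent/malformed."""
    m = re.match(r"^(\d+);(\d+)(?:\.(\d+))?", age.strip())
    if not m:
        return None
    years, months = int(m.group(1)), int(m.group(2))
    days = int(m.group(3)) if m.group(3) else 0
    return 12 * years + months + days / 30.0


@dataclass
class ChatDocument:
    """One parsed transcript: speaker utterances plus child metadata."""

    utterances: list[tuple[str, list[str]]]  # (speaker code, tokens)
    child_code: str
    child_age_months: "float | None"

    def count_word(self, word: str, exclude_child: bool = True) -> int:
        """Case-insensitive exact orthographic token count."""
        w = word.casefold()
        total = 0
        for spk, tokens in self.utterances:
            if exclude_child and spk == self.child_code:
                continue
            total += sum(1 for t in tokens if t == w)
        return total


def make_chat_fixture(
    word_counts: Mapping[str, Mapping[str, int]],
    child_age_months: float,
    language: str = "deu",
    corpus: str = "synthetic",
) -> str:
    """Build a minimal valid CHAT document embedding each word exactly the
    requested number of times per speaker.

    ``word_counts`` maps word -> {speaker code -> count}; the target child's
    code is CHI.  All data are synthetic (this is a generated stand-in for a
    real corpus transcript).
    """
    age = format_age(child_age_months)
    speakers = sorted({spk for per in word_counts.values() for spk in per} | {"CHI"})
    roles = {spk: ("Target_Child" if spk == "CHI" else "Adult") for spk in speakers}
    lines = [
        "@UTF8",
        "@Begin",
        f"@Languages:\t{language}",
        "@Participants:\t" + " , ".join(f"{s} {roles[s]}" for s in speakers),
    ]
    for s in speakers:
        a = age if s == "CHI" else ""
        lines.append(f"@ID:\t{language}|{corpus}|{s}|{a}|||{roles[s]}|||")
    for word in sorted(word_counts):
        for spk in sorted(word_counts[word]):
            n = int(word_counts[word][spk])
            if n < 0:
                raise ChatError(f"negative count for {word!r}/{spk}")
            # Chunk long repetitions into utterances of at most 10 tokens.
            while n > 0:
                chunk = min(n, 10)
                lines.append(f"*{spk}:\t" + " ".join([word] * chunk) + " .")
                n -= chunk
    lines.append("@End")
    return "\n".join(lines) + "\n"


def _tokenize(text: str) -> list[str]:
    tokens = []
    for raw in text.split():
        if raw.startswith(("[", "&", "%", "@", "+")) or _PUNCT.match(raw):
            continue
        tok = _STRIP.sub("", raw).casefold()
        if tok:
            tokens.append(tok)
    return tokens


def parse_chat(text: str) -> ChatDocument:
    """Parse a CHAT document string.

    The target child is the speaker with role Target_Child in @ID (falling
    back to code CHI); the age comes from that @ID record's age field.
    """
    if "@Begin" not in text and "@Participants" not in text and "@ID" not in text:
        raise ChatError("not a CHAT document (no @Begin/@Participants/@ID header)")
    child_code = "CHI"
    child_age: "float | None" = None
    utterances: list[tuple[str, list[str]]] = []
    current: "tuple[str, list[str]] | None" = None

    for line in text.splitlines():
        if line.startswith("@ID:"):
            fields = line.split(":", 1)[1].strip().split("|")
            if len(fields) >= 7 and "Target_Child" in fields[6:8]:
                child_code = fields[2]
            if len(fields) >= 4 and fields[2] == child_code and fields[3]:
                child_age = parse_age(fields[3])
            current = None
        elif line.startswith("*"):
            head, _, rest = line.partition(":")
            spk = head[1:].strip()
            current = (spk, _tokenize(rest))
            utterances.append(current)
        elif line.startswith(("\t", " ")) and current is not None:
            current[1].extend(_tokenize(line))
        else:
            current = None
    return ChatDocument(utterances=utterances, child_code=child_code,
                        child_age_months=child_age)
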