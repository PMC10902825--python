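"""Ordered phrase-rule engine for free-text report sections.

Each categorical variable is classified by an ordered :class:`VariableRuleSet`:
rules are evaluated by ascending priority and the first match wins; if nothing
matches the variable's default level is returned.  Two rule kinds exist:

``direct``
    A consecutive-phrase pattern (a small case-insensitive regex; literal
    spaces match any whitespace run) searched over the whole text.  These
    encode explicit wordings such as "mild regurgitation" and always run
    before any catch-all.

``catch_all``
    Whitespace-separated tokens that must all occur (as whole words, each
    token may be an alternation like ``mild|mildly``) within one sentence.
    Sentences are delimited by ``.``, ``;`` and newlines.  These encode
    co-occurrence logic: "moderate" and "regurgitation" in the same sentence
    means moderate regurgitation — unless a direct rule already fired, which
    is how "mild regurgitation and moderate stenosis" stays mild.

Text is normalised before matching: lower-cased, with hyphens and dashes
replaced by spaces (so "mild-to-moderate" and "mild to moderate" are the
same phrase).  Normalisation preserves character positions, so the matched
span reported for auditing is always a substring of the original input.

Rule sets are data, not code: the defaults ship as a YAML document
(``echoclean/data/default_rules.yaml``) that a laboratory can copy and
re-tune to its own reporting dialect, mirroring the iterative
phrase-development loop used to build them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import yaml

from .errors import ConfigurationError
from .schema import EXCLUDE

DEFAULT_RULE = "DEFAULT"

_DASHES = "‐‑‒–—-"
_SENTENCE_SPLIT = re.compile(r"[^.;\n]+")


def normalize(text: str) -> str:
    """Lower-case and replace hyphens/dashes with spaces, preserving length."""
    out = text.lower()
    for ch in _DASHES:
        out = out.replace(ch, " ")
    return out


def _compile_direct(pattern: str) -> re.Pattern:
    body = re.sub(r" +", r"\\s+", pattern.strip())
    return re.compile(r"\b(?:%s)\b" % body)


def _compile_tokens(pattern: str) -> list[re.Pattern]:
    return [re.compile(r"\b(?:%s)\b" % tok) for tok in pattern.split()]


@dataclass(frozen=True)
class PhraseRule:
    """One text pattern mapping to one category level."""

    pattern: str
    level: str
    priority: int
    scope: str = "whole_text"  # or "sentence"
    kind: str = "direct"  # or "catch_all"

    def __post_init__(self):
        if not self.pattern.strip():
            raise ConfigurationError("PhraseRule.pattern must be non-empty")
        if self.kind not in ("direct", "catch_all"):
            raise ConfigurationError(f"unknown rule kind {self.kind!r}")
        if self.scope not in ("whole_text", "sentence"):
            raise ConfigurationError(f"unknown rule scope {self.scope!r}")
        try:
            if self.kind == "direct":
                object.__setattr__(self, "_rx", _compile_direct(self.pattern))
            else:
                object.__setattr__(self, "_tokens", _compile_tokens(self.pattern))
        except re.error as exc:
            raise ConfigurationError(
                f"invalid pattern {self.pattern!r}: {exc}"
            ) from exc

    def __str__(self) -> str:  # audit log identity
        return f"{self.kind}[{self.priority}]:{self.pattern!r}->{self.level}"


@dataclass(frozen=True)
class Classification:
    """Outcome of one classify call, auditable down to the matched fragment."""

    level: str
    matched_rule: str  # str(PhraseRule) or DEFAULT_RULE
    matched_span: str


@dataclass
class VariableRuleSet:
    """Ordered rules, level set and default level for one variable."""

    variable: str
    levels: list[str]
    default: str
    rules: list[PhraseRule] = field(default_factory=list)

    def __post_init__(self):
        allowed = set(self.levels) | {EXCLUDE}
        if self.default not in allowed:
            raise ConfigurationError(
                f"{self.variable}: default level {self.default!r} not in level set"
            )
        prios = [r.priority for r in self.rules]
        if len(prios) != len(set(prios)):
            raise ConfigurationError(
                f"{self.variable}: rule priorities must be strictly ordered"
            )
        for r in self.rules:
            if r.level not in allowed:
                raise ConfigurationError(
                    f"{self.variable}: rule level {r.level!r} not in level set"
                )
        ordered = sorted(self.rules, key=lambda r: r.priority)
        directs = [r.priority for r in ordered if r.kind == "direct"]
        catchalls = [r.priority for r in ordered if r.kind == "catch_all"]
        if directs and catchalls and max(directs) > min(catchalls):
            raise ConfigurationError(
                f"{self.variable}: direct rules must all precede catch-all rules"
            )
        self.rules = ordered


def classify(text: Optional[str], rules: VariableRuleSet) -> Classification:
    """Classify one free-text section; pure function of (text, rules)."""
    if text is None or not text.strip():
        return Classification(rules.default, DEFAULT_RULE, "")
    norm = normalize(text)
    sentences = None
    for rule in rules.rules:
        if rule.kind == "direct" and rule.scope == "whole_text":
            m = rule._rx.search(norm)
            if m:
                return Classification(rule.level, str(rule), text[m.start():m.end()])
        else:
            if sentences is None:
                sentences = [(m.start(), m.end()) for m in _SENTENCE_SPLIT.finditer(norm)]
            for start, end in sentences:
                seg = norm[start:end]
                if rule.kind == "catch_all":
                    hit = all(t.search(seg) for t in rule._tokens)
                else:  # direct rule restricted to one sentence
                    hit = rule._rx.search(seg) is not None
                if hit:
                    return Classification(rule.level, str(rule), text[start:end].strip())
    return Classification(rules.default, DEFAULT_RULE, "")


# ---------------------------------------------------------------------------
# Rule-set (de)serialisation
# ---------------------------------------------------------------------------

def rulesets_from_dict(doc: Mapping) -> dict[str, VariableRuleSet]:
    out = {}
    for name, spec in doc.items():
        try:
            rules = [
                PhraseRule(
                    pattern=r["pattern"],
                    level=str(r["level"]),
                    priority=int(r["priority"]),
                    scope=r.get("scope", "whole_text"),
                    kind=r.get("kind", "direct"),
                )
                for r in spec.get("rules", [])
            ]
            out[name] = VariableRuleSet(
                variable=name,
                levels=[str(l) for l in spec["levels"]],
                default=str(spec["default"]),
                rules=rules,
            )
        except KeyError as exc:
            raise ConfigurationError(f"rule set {name!r}: missing key {exc}") from exc
    return out


def rulesets_to_dict(rulesets: Mapping[str, VariableRuleSet]) -> dict:
    return {
        name: {
            "levels": rs.levels,
            "default": rs.default,
            "rules": [
                {"pattern": r.pattern, "level": r.level, "priority": r.priority,
                 "scope": r.scope, "kind": r.kind}
                for r in rs.rules
            ],
        }
        for name, rs in rulesets.items()
    }


def load_rulesets(path: Optional[str] = None) -> dict[str, VariableRuleSet]:
    """Load rule sets from a YAML file, or the shipped defaults."""
    if path is None:
        text = (resources.files("echoclean.data") / "default_rules.yaml").read_text(
            encoding="utf-8"
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ConfigurationError("rule file must map variable names to rule sets")
    return rulesets_from_dict(doc)


def save_rulesets(rulesets: Mapping[str, VariableRuleSet], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rulesets_to_dict(rulesets), fh, sort_keys=False,
                       allow_unicode=True)


_DEFAULT_CACHE: dict[str, VariableRuleSet] = {}


def default_rulesets() -> dict[str, VariableRuleSet]:
    """The shipped rule sets (cached)."""
    if not _DEFAULT_CACHE:
        _DEFAULT_CACHE.update(load_rulesets())
    return _DEFAULT_CACHE


def rule_keywords(rulesets: Optional[Mapping[str, VariableRuleSet]] = None) -> set[str]:
    """All alphabetic words appearing in rule patterns.

    The synthetic generator treats these as protected "keyword" tokens: default
    typo injection never touches them, so rule coverage rather than noise
    decides whether a label is recoverable.
    """
    if rulesets is None:
        rulesets = default_rulesets()
    words: set[str] = set()
    for rs in rulesets.values():
        for r in rs.rules:
            for w in re.findall(r"[a-z]+", r.pattern.lower()):
                words.add(w)
    words.discard("w")  # regex shorthand \w, not a vocabulary word
    words.discard("s")
    return words
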