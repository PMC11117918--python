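"""Compile anomaly-detection text corpora and ensemble them into anchors.

Zero-shot anomaly scoring needs two text prototypes: one describing the
normal state of the imaged object and one describing the abnormal state.
Rather than calling a language model, prompts are compiled deterministically
from templates crossed with state-descriptor lexicons. Two template scopes
exist:

* ``spd`` — specific image descriptions, class-dependent, e.g.
  "A medical photo of a healthy brain";
* ``cad`` — category-agnostic descriptions with no class mention, e.g.
  "A medical photo of something normal".

Externally generated prompt text (for instance from a language model run
elsewhere) can be imported from a plain-text file instead.

The two anchors of a :class:`TextBank` are the L2-normalized arithmetic
means of the encoded normal and abnormal prompt lists (prompt ensembling).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Template",
    "DescriptorLexicon",
    "PromptSet",
    "TextBank",
    "expand_templates",
    "import_prompts",
    "build_text_bank",
    "DEFAULT_TEMPLATES",
    "DEFAULT_LEXICON",
]


class PromptConfigError(ValueError):
    """A prompt configuration violates its contract."""


@dataclass(frozen=True)
class Template:
    """A prompt pattern with ``{domain}``, ``{state}`` and ``{class}`` slots."""

    pattern: str
    scope: str  # "spd" (class-dependent) or "cad" (class-agnostic)

    def __post_init__(self):
        if self.scope not in ("spd", "cad"):
            raise PromptConfigError(f"unknown template scope {self.scope!r}")
        if "{state}" not in self.pattern:
            raise PromptConfigError("every template must contain {state}")
        has_class = "{class}" in self.pattern
        if self.scope == "spd" and not has_class:
            raise PromptConfigError("spd templates must contain {class}")
        if self.scope == "cad" and has_class:
            raise PromptConfigError("cad templates must not contain {class}")

    def fill(self, state: str, class_name: str | None, domain: str) -> str:
        out = self.pattern.replace("{domain}", domain).replace("{state}", state)
        if self.scope == "spd":
            out = out.replace("{class}", class_name or "")
        return _normalize_ws(out)


@dataclass(frozen=True)
class DescriptorLexicon:
    """Disjoint non-empty lists of normal- and abnormal-state descriptors."""

    normal_states: tuple[str, ...]
    abnormal_states: tuple[str, ...]

    def __post_init__(self):
        for name, states in (("normal", self.normal_states), ("abnormal", self.abnormal_states)):
            if not states:
                raise PromptConfigError(f"{name}_states must be non-empty")
            if any(not s.strip() for s in states):
                raise PromptConfigError(f"{name}_states contains an empty descriptor")
        if set(self.normal_states) & set(self.abnormal_states):
            raise PromptConfigError("normal and abnormal descriptors must be disjoint")


@dataclass
class PromptSet:
    normal_prompts: list[str]
    abnormal_prompts: list[str]
    class_name: str | None = None
    provenance: str = "compiled"  # or "imported"

    def __post_init__(self):
        self.normal_prompts = _dedup(self.normal_prompts)
        self.abnormal_prompts = _dedup(self.abnormal_prompts)
        if not self.normal_prompts or not self.abnormal_prompts:
            raise PromptConfigError("prompt set needs normal and abnormal prompts")


@dataclass
class TextBank:
    """The two unit-norm prototype vectors anchoring all anomaly scoring."""

    f_normal: np.ndarray
    f_abnormal: np.ndarray

    def __post_init__(self):
        if self.f_normal.shape != self.f_abnormal.shape:
            raise ValueError("anchor dimensions differ")
        for v in (self.f_normal, self.f_abnormal):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError("text-bank anchors must be unit-norm")


def _normalize_ws(s: str) -> str:
    return re.sub(r"\s+", " ", s).strip()


def _dedup(items) -> list[str]:
    seen, out = set(), []
    for it in items:
        key = _normalize_ws(it)
        if key and key not in seen:
            seen.add(key)
            out.append(key)
    return out


#: seed templates; the spd pattern mirrors "A [domain] photo of a [state] [class]"
#: and the cad pattern its class-free counterpart.
DEFAULT_TEMPLATES = (
    Template("A {domain} photo of a {state} {class}.", "spd"),
    Template("An image of a {state} {class}.", "spd"),
    Template("A {domain} photo of something {state}.", "cad"),
    Template("An image showing {state} tissue.", "cad"),
)

#: seed descriptor lexicon for medical-style imagery, user-extensible.
DEFAULT_LEXICON = DescriptorLexicon(
    normal_states=("normal", "healthy", "intact", "unremarkable", "regular",
                   "enhanced contrast", "intact structure"),
    abnormal_states=("abnormal", "anomalous", "diseased", "lesions", "calcifications",
                     "tumor", "presence of lesions", "indications of calcifications"),
)


def expand_templates(
    templates,
    lexicon: DescriptorLexicon,
    class_name: str | None = None,
    domain: str = "medical",
) -> PromptSet:
    """Cross every template with every state descriptor.

    spd and cad prompts are pooled into a single corpus (T = T_spd + T_cad);
    use :func:`filter_scope` beforehand to ablate either scope. The prompt
    count law |normal_prompts| = n_templates x |normal_states| holds exactly
    before deduplication, and deduplication only collapses genuinely
    identical strings.
    """
    templates = list(templates)
    if not templates:
        raise PromptConfigError("at least one template required")
    if any(t.scope == "spd" for t in templates) and not (class_name and class_name.strip()):
        raise PromptConfigError("spd templates require a class name")
    normal = [t.fill(s, class_name, domain) for t in templates for s in lexicon.normal_states]
    abnormal = [t.fill(s, class_name, domain) for t in templates for s in lexicon.abnormal_states]
    return PromptSet(normal_prompts=normal, abnormal_prompts=abnormal,
                     class_name=class_name, provenance="compiled")


def filter_scope(templates, scope: str):
    """Restrict a template list to one scope ("spd" or "cad")."""
    if scope not in ("spd", "cad", "both"):
        raise PromptConfigError(f"unknown scope {scope!r}")
    if scope == "both":
        return list(templates)
    return [t for t in templates if t.scope == scope]


def import_prompts(path: str | Path, class_name: str | None = None) -> PromptSet:
    """Read externally generated prompts from a sectioned plain-text file.

    The file lists one prompt per line under ``# normal`` and ``# abnormal``
    section headers; both sections are required. Lines are whitespace-
    normalized and deduplicated.
    """
    text = Path(path).read_text()
    if not text.strip():
        raise PromptConfigError(f"prompt file {path} is empty")
    sections: dict[str, list[str]] = {}
    current: str | None = None
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        m = re.match(r"#\s*(normal|abnormal)\b", stripped, flags=re.IGNORECASE)
        if m:
            current = m.group(1).lower()
            sections.setdefault(current, [])
            continue
        if stripped.startswith("#"):
            continue  # comment
        if current is None:
            raise PromptConfigError("prompt line before any '# normal'/'# abnormal' header")
        sections[current].append(stripped)
    missing = {"normal", "abnormal"} - set(sections)
    if missing:
        raise PromptConfigError(f"prompt file missing section(s): {sorted(missing)}")
    return PromptSet(normal_prompts=sections["normal"], abnormal_prompts=sections["abnormal"],
                     class_name=class_name, provenance="imported")


def build_text_bank(prompts: PromptSet, text_encoder) -> TextBank:
    """Ensemble prompt embeddings into the two scoring anchors.

    f_normal (resp. f_abnormal) is the L2-normalized arithmetic mean of the
    encoded normal (resp. abnormal) prompts; order of prompts is irrelevant
    up to floating-point summation order.
    """

    def _ensemble(lines: list[str]) -> np.ndarray:
        vecs = [np.asarray(text_encoder(p), dtype=float) for p in lines]
        dims = {v.shape for v in vecs}
        if len(dims) != 1:
            raise ValueError(f"text encoder returned inconsistent dims: {dims}")
        mean = np.mean(vecs, axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-9:
            raise ValueError("prompt embeddings cancel out; cannot build an anchor")
        return mean / norm

    return TextBank(f_normal=_ensemble(prompts.normal_prompts),
                    f_abnormal=_ensemble(prompts.abnormal_prompts))
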