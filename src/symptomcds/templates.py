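"""Recommendation templates and the binding registry.

A template is plain text with ``{slot}`` markers plus a named *binding*: a
deterministic function of the evaluation context that supplies every slot
value and the structured dose fields.  Templates hold no logic of their own —
all branching lives in decision nodes and all arithmetic in the calculators.

``requires`` lists the raw patient variables a binding reads, so the
completeness gate can demand them up front.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

__all__ = ["RecommendationTemplate", "register_template", "get_template", "template_requires"]


@dataclass(frozen=True)
class RecommendationTemplate:
    id: str
    category: str
    text: str
    binding: Callable[[Mapping[str, Any]], Mapping[str, Any] | None] | None = None
    requires: tuple[str, ...] = ()
    #: static structured fields merged under the binding's output
    fields: Mapping[str, Any] = field(default_factory=dict)


_REGISTRY: dict[str, RecommendationTemplate] = {}


def register_template(template: RecommendationTemplate) -> RecommendationTemplate:
    if template.id in _REGISTRY and _REGISTRY[template.id] is not template:
        raise ValueError(f"duplicate template id {template.id!r}")
    _REGISTRY[template.id] = template
    return template


def get_template(template_id: str) -> RecommendationTemplate:
    try:
        return _REGISTRY[template_id]
    except KeyError:
        raise KeyError(f"unknown recommendation template {template_id!r}") from None


def template_requires(template_id: str) -> tuple[str, ...]:
    """Raw variables a template's binding reads (empty for unknown ids so
    structural validation can flag the dangling reference instead)."""
    t = _REGISTRY.get(template_id)
    return t.requires if t is not None else ()


def known_template(template_id: str) -> bool:
    return template_id in _REGISTRY
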