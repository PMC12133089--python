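"""Stage 1 of the agent: prompt building, LLM backends, response parsing.

The agent first asks a language model for a short ranked list of candidate
cell types given a cluster's marker genes plus tissue and species context.
The prompt is deliberately constrained — names only, one per line — so that
parsing is robust; candidates are later verified against measured
expression, which is what makes the overall call trustworthy.

Backends are pluggable behind :class:`LLMBackend`.  Tests and offline runs
use :class:`ScriptedBackend` (deterministic given a seed); a minimal
OpenAI-compatible HTTP client is provided for real runs, with credentials
supplied only via environment-variable indirection.

Every prompt/response pair can be persisted to a JSON-lines audit log so
the full decision trail is inspectable after the fact.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
import re
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence, runtime_checkable

from .errors import ConfigurationError, InferenceError, ResponseParseError
from .markers import MarkerSet

#: Default number of candidates requested per cluster; three gives a small
#: but meaningful shortlist for verification and performed best in sweeps.
DEFAULT_K = 3
DEFAULT_MAX_RETRIES = 2

_FORMAT_REMINDER = ("\n\nReminder: respond ONLY with cell type names, "
                    "one name per line, nothing else.")


@dataclass(frozen=True)
class Prompt:
    """A fully rendered annotation prompt with its request context."""

    text: str
    k: int
    mode: str  # single | mixture
    context: tuple[str, str, tuple[str, ...]]  # (tissue, species, genes)


@runtime_checkable
class LLMBackend(Protocol):
    """Behavioral contract for a completion backend."""

    identity: str

    def complete(self, prompt: str, temperature: float = 0.0,
                 seed: int | None = None) -> str: ...


class ScriptedBackend:
    """Deterministic backend driven by a response function or canned list.

    Given the same seed and prompt, ``complete`` returns byte-identical
    text; this is the mock used for offline pipelines and tests.
    """

    def __init__(self, responder: Callable[[str], str] | Sequence[str],
                 identity: str = "scripted"):
        if callable(responder):
            self._fn = responder
        else:
            canned = list(responder)
            state = {"i": 0}

            def _fn(prompt: str) -> str:
                text = canned[min(state["i"], len(canned) - 1)]
                state["i"] += 1
                return text
            self._fn = _fn
        self.identity = identity

    def complete(self, prompt: str, temperature: float = 0.0,
                 seed: int | None = None) -> str:
        return self._fn(prompt)


class OpenAICompatBackend:
    """Minimal chat-completions client for OpenAI-compatible endpoints.

    The API key is read from the environment variable named by
    ``api_key_env`` at call time; keys never live in config files.  Network
    access is entirely optional — nothing in the package requires this
    backend.
    """

    def __init__(self, model: str, endpoint: str = "https://api.openai.com/v1/chat/completions",
                 api_key_env: str = "OPENAI_API_KEY", timeout: float = 60.0):
        self.identity = model
        self.endpoint = endpoint
        self.api_key_env = api_key_env
        self.timeout = timeout

    def complete(self, prompt: str, temperature: float = 0.0,
                 seed: int | None = None) -> str:
        key = os.environ.get(self.api_key_env)
        if not key:
            raise ConfigurationError(
                f"environment variable {self.api_key_env} is not set")
        body = {"model": self.identity, "temperature": temperature,
                "messages": [{"role": "user", "content": prompt}]}
        if seed is not None:
            body["seed"] = seed
        req = urllib.request.Request(
            self.endpoint, data=json.dumps(body).encode(),
            headers={"Content-Type": "application/json",
                     "Authorization": f"Bearer {key}"})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            payload = json.load(resp)
        return payload["choices"][0]["message"]["content"]


@dataclass(frozen=True)
class CandidateList:
    """Ranked candidate cell types for one cluster (index 0 = top)."""

    cluster_id: str
    candidates: tuple[str, ...]
    raw_response: str
    model: str
    attempts: int = 1


class AuditLog:
    """JSON-lines audit trail of every backend call.

    One record per call: timestamp, cluster_id, prompt, response, model,
    attempt.  Appending is the only operation; the file is the artifact.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def record(self, **fields) -> None:
        rec = {"timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(), **fields}
        with self.path.open("a") as fh:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def build_prompt(marker_set: MarkerSet, k: int = DEFAULT_K,
                 mode: str = "single") -> Prompt:
    """Render the annotation prompt for one cluster.

    Single mode asks for exactly ``k`` ranked cell types; mixture mode
    states that the markers may come from a mixture of multiple cell types
    and asks for all plausible component types (still capped at ``k`` when
    parsed).  The prompt contains every marker gene exactly once.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    if mode not in ("single", "mixture"):
        raise ConfigurationError(f"mode must be 'single' or 'mixture', got {mode!r}")
    genes = ", ".join(marker_set.genes)
    head = (f"You are annotating a cell cluster from single-cell RNA-seq data.\n"
            f"Species: {marker_set.species}\n"
            f"Tissue: {marker_set.tissue}\n"
            f"Top marker genes for this cluster (highest-ranked first): {genes}\n")
    if mode == "single":
        ask = (f"List the {k} most likely cell types for this cluster, ranked from "
               f"most to least likely.\n"
               f"Respond with exactly {k} cell type names, one per line, "
               f"no numbering, no explanations.")
    else:
        ask = ("These marker genes may come from a MIXTURE of multiple cell types "
               "present in the same cluster.\n"
               "List every cell type plausibly contributing to this marker set, "
               "most prominent first.\n"
               "Respond with cell type names only, one per line, no explanations.")
    return Prompt(text=head + ask, k=k, mode=mode,
                  context=(marker_set.tissue, marker_set.species, marker_set.genes))


_LIST_ITEM = re.compile(r"^\s*(?:[-*•‣◦]|\(?\d{1,3}[.):])\s+(.*\S)\s*$")
_REFUSAL_HINTS = ("cannot", "unable", "sorry", "as an ai", "i'm not", "i am not")


def _clean_name(raw: str) -> str:
    s = raw.strip()
    # alternate stripping of trailing punctuation and paired markdown
    # emphasis ("**Name.**", "*Name*;"); underscores inside names survive
    for _ in range(3):
        s = s.strip(" \t'\"")
        s = re.sub(r"[.,;:]+$", "", s).strip()
        for tok in ("**", "__", "*", "_", "`"):
            while len(s) > 2 * len(tok) and s.startswith(tok) and s.endswith(tok):
                s = s[len(tok):-len(tok)].strip()
    return s.lstrip("*`").strip()


def _plausible_plain_line(line: str) -> bool:
    if len(line.split()) > 6:
        return False
    low = line.lower()
    if any(h in low for h in _REFUSAL_HINTS):
        return False
    return not line.endswith(("?", ":"))


def parse_candidates(text: str, k: int = DEFAULT_K) -> list[str]:
    """Extract up to ``k`` candidate names from an LLM response.

    Handles numbered, bulleted and plain line-separated lists; strips list
    markers, trailing punctuation and markdown emphasis; preserves the
    stated ranking.  Raises :class:`ResponseParseError` when nothing
    name-like can be extracted (prose, refusals), signalling a retry.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    names: list[str] = []
    marked = [m.group(1) for m in (_LIST_ITEM.match(ln) for ln in lines) if m]
    if marked:
        names = [_clean_name(x) for x in marked]
    else:
        names = [_clean_name(ln) for ln in lines if _plausible_plain_line(ln.strip())]
    names = [n for n in names if n]
    if not names:
        raise ResponseParseError(f"no candidate cell-type names found in response: {text!r}")
    return names[:k]


def infer_candidates(backend: LLMBackend, marker_set: MarkerSet,
                     k: int = DEFAULT_K, mode: str = "single",
                     max_retries: int = DEFAULT_MAX_RETRIES,
                     temperature: float = 0.0, seed: int | None = None,
                     audit: AuditLog | None = None) -> CandidateList:
    """Run stage 1 for one cluster: prompt, complete, parse, retry.

    On a parse failure the prompt is re-sent with an appended format
    reminder, up to ``max_retries`` extra attempts.  The returned
    :class:`CandidateList` records the raw response of the successful call
    and the number of attempts; exhaustion raises :class:`InferenceError`
    carrying the last raw response.
    """
    if max_retries < 0:
        raise ConfigurationError(f"max_retries must be >= 0, got {max_retries}")
    prompt = build_prompt(marker_set, k=k, mode=mode)
    last_raw = ""
    for attempt in range(1, max_retries + 2):
        text = prompt.text if attempt == 1 else prompt.text + _FORMAT_REMINDER
        raw = backend.complete(text, temperature=temperature, seed=seed)
        last_raw = raw
        if audit is not None:
            audit.record(cluster_id=marker_set.cluster_id, prompt=text,
                         response=raw, model=backend.identity, attempt=attempt)
        try:
            names = parse_candidates(raw, k=k)
        except ResponseParseError:
            continue
        return CandidateList(cluster_id=marker_set.cluster_id,
                             candidates=tuple(names), raw_response=raw,
                             model=backend.identity, attempts=attempt)
    raise InferenceError(
        f"no parseable candidate list for cluster {marker_set.cluster_id!r} "
        f"after {max_retries + 1} attempt(s)",
        raw_response=last_raw, attempts=max_retries + 1)
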