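"""RESTful annotation service over the pipeline (plain WSGI).

Endpoints:

* ``POST /annotate`` — body: BioC XML; query parameters ``types``
  (comma-separated entity types), ``relations`` (comma-separated
  ``type1-type2`` pairs), ``mode`` (``standoff``, the default, or
  ``inline``), ``filter`` (sentence-filter expression, URL-encoded),
  ``lexicon`` (identifier of a pre-loaded vocabulary),
  ``include_offsets`` (``true``/``false``).  Response: the same
  collection enriched with scored annotations and ranked relations, in
  BioC XML.
* ``GET /lexicons`` — JSON list of the pre-loaded vocabularies.

The service is stateless: identical requests produce byte-identical
responses.  Documents can in principle be fetched by PubMed identifier
through a pluggable fetcher hook; none is installed by default, so
payloads must embed their text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional
from urllib.parse import parse_qs, unquote

from lxml import etree

from . import filters
from .bioc import BioCValidationError, read_bioc, write_bioc
from .pipeline import PipelineConfig, process_collection
from .relations import PatternTable
from .terminology import Lexicon

__all__ = ["AnnotationService", "create_wsgi_app", "serve"]

DEFAULT_PAYLOAD_LIMIT = 2 * 1024 * 1024  # bytes


@dataclass
class AnnotationService:
    """Request handling shared by the WSGI app and direct callers."""

    lexicons: Dict[str, Lexicon]
    default_lexicon: str
    config: PipelineConfig = field(default_factory=PipelineConfig)
    patterns: Optional[PatternTable] = None
    parses_provider: Optional[Callable] = None   # collection -> {doc_id: trees}
    document_fetcher: Optional[Callable] = None  # pmid -> BioCDocument (disabled)
    payload_limit: int = DEFAULT_PAYLOAD_LIMIT

    def handle(self, method: str, path: str, query: str, body: bytes):
        """Dispatch a request; returns (status, content_type, payload bytes)."""
        try:
            if method == "GET" and path == "/lexicons":
                return self._lexicon_list()
            if method == "POST" and path == "/annotate":
                return self._annotate(query, body)
            return self._error(404, f"no such endpoint: {method} {path}")
        except BioCValidationError as exc:
            return self._error(400, f"invalid BioC payload: {exc}")
        except etree.XMLSyntaxError as exc:
            return self._error(400, f"malformed XML: {exc}")
        except filters.FilterSyntaxError as exc:
            return self._error(400, f"bad filter expression: {exc}")
        except ValueError as exc:
            return self._error(400, str(exc))

    # -- endpoints ---------------------------------------------------------

    def _lexicon_list(self):
        payload = json.dumps(
            [{"id": name, "entries": len(lex), "types": sorted(lex.types_available)}
             for name, lex in sorted(self.lexicons.items())],
            sort_keys=True,
        ).encode("utf-8")
        return 200, "application/json", payload

    def _annotate(self, query: str, body: bytes):
        if len(body) > self.payload_limit:
            return self._error(413, f"payload exceeds {self.payload_limit} bytes")
        params = {k: v[-1] for k, v in parse_qs(query, keep_blank_values=True).items()}

        lexicon_id = params.get("lexicon", self.default_lexicon)
        if lexicon_id not in self.lexicons:
            return self._error(
                400,
                f"unknown lexicon '{lexicon_id}'; available: "
                + ", ".join(sorted(self.lexicons)),
            )
        lexicon = self.lexicons[lexicon_id]

        mode = params.get("mode", "standoff")
        if mode not in ("standoff", "inline"):
            return self._error(400, f"mode must be standoff or inline, got '{mode}'")

        config = replace(self.config)
        if params.get("types"):
            requested = set(params["types"].split(","))
            unknown = requested - lexicon.types_available
            if unknown:
                return self._error(400, f"unknown entity types: {', '.join(sorted(unknown))}")
            config.entity_types = requested
        if params.get("relations"):
            config.relation_pairs = {
                frozenset(pair.split("-")) for pair in params["relations"].split(",")
            }

        collection = read_bioc(body)
        parses = self.parses_provider(collection) if self.parses_provider else None
        result = process_collection(collection, lexicon, config,
                                    parses=parses, patterns=self.patterns)
        out = result.collection

        if params.get("filter"):
            expr = filters.parse_filter(unquote(params["filter"]),
                                        known_types=lexicon.types_available)
            for doc in out.documents:
                selected, ratio = filters.apply_filter(doc, expr)
                doc.infons["filter_selected"] = ",".join(str(i) for i in selected)
                doc.infons["filter_reduction_ratio"] = f"{ratio:.6f}"

        include_offsets = params.get("include_offsets", "true").lower() != "false"
        if not include_offsets:
            for doc in out.documents:
                for ann in doc.annotations():
                    ann.locations = []

        xml = write_bioc(out, mode=mode, overlap_policy="longest-wins")
        return 200, "application/xml", xml.encode("utf-8")

    @staticmethod
    def _error(status: int, message: str):
        return status, "application/json", json.dumps({"error": message}).encode("utf-8")


_STATUS_TEXT = {200: "OK", 400: "Bad Request", 404: "Not Found",
                413: "Payload Too Large", 500: "Internal Server Error"}


def create_wsgi_app(service: AnnotationService):
    """Wrap an :class:`AnnotationService` as a WSGI callable."""

    def app(environ, start_response):
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        body = environ["wsgi.input"].read(length) if length else b""
        status, ctype, payload = service.handle(
            environ.get("REQUEST_METHOD", "GET"),
            environ.get("PATH_INFO", "/"),
            environ.get("QUERY_STRING", ""),
            body,
        )
        start_response(
            f"{status} {_STATUS_TEXT.get(status, 'Unknown')}",
            [("Content-Type", ctype), ("Content-Length", str(len(payload)))],
        )
        return [payload]

    return app


def serve(service: AnnotationService, host: str = "127.0.0.1", port: int = 8080):
    """Run the service with the reference WSGI server (blocking)."""
    from wsgiref.simple_server import make_server

    with make_server(host, port, create_wsgi_app(service)) as httpd:
        httpd.serve_forever()
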