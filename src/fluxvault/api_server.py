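"""HTTP query API and action-schema handshake.

URL convention: after host and port, the first path segment names the query
and any further segments are its parameters —
``/<queryName>[/<param>...]``.  Reads are GET; ``saveModificationFile`` is a
POST whose body is the YAML modification file (a save cannot be a pure
path).  For ``solveFBA`` each extra path segment after the model id names a
modification file, and URL order **is** load order, so the last-loaded-wins
override rule is reproducible over HTTP.

A client declares, per module, the set of server commands that module
requires (its action schema); before unlocking a module it checks that set
against the server's self-description at ``/commands``.  The server here
always lists every route it actually serves, so a handshake against itself
unlocks everything.

Responses are JSON except ``importViewFile``, which returns the raw view
document under its own media type.  An infeasible FBA is a *result*
(HTTP 200, status "infeasible"), not a transport error.  The server never
writes to a model file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Iterable, Mapping
from wsgiref.simple_server import make_server

from .errors import (
    ConflictError,
    ConsistencyError,
    FluxVaultError,
    FormatError,
    LineageError,
    MissingReferenceError,
    NotFoundError,
)
from .fba_engine import build_problem, solve_fba
from .model_store import ModelStore
from .modification_trace import parse_modification_file, resolve_effective_state

__all__ = [
    "ActionSchema",
    "ServerCommandList",
    "check_action_schema",
    "QueryServer",
    "wsgi_app",
    "serve",
]

log = logging.getLogger("fluxvault.api")

CYJS_MEDIA_TYPE = "application/vnd.cytoscape.cyjs+json"


@dataclass(frozen=True)
class ActionSchema:
    """Per-module sets of server commands a client requires."""

    modules: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for module, commands in self.modules.items():
            for cmd in commands:
                if not cmd:
                    raise FormatError(f"module {module!r}: empty command name")


@dataclass(frozen=True)
class ServerCommandList:
    commands: frozenset[str]


def check_action_schema(
    schema: ActionSchema, commands: ServerCommandList
) -> dict[str, bool]:
    """Handshake: a module unlocks iff its required set is a subset of the
    server's command list (an empty requirement unlocks vacuously)."""
    return {
        module: required <= commands.commands
        for module, required in schema.modules.items()
    }


class QueryServer:
    """Transport-independent request handling over one :class:`ModelStore`.

    ``handle(method, path, body)`` returns ``(status, media_type, payload
    bytes)``; the WSGI adapter below is a thin shim over it, so tests can
    exercise the full routing logic in-process.
    """

    def __init__(self, store: ModelStore):
        self.store = store

    # registered query name -> (http method, handler taking param segments)
    @property
    def commands(self) -> ServerCommandList:
        return ServerCommandList(frozenset(self._routes()))

    def _routes(self) -> dict[str, tuple[str, Callable]]:
        return {
            "commands": ("GET", self._q_commands),
            "listModels": ("GET", self._q_list_models),
            "listViews": ("GET", self._q_list_views),
            "importViewFile": ("GET", self._q_import_view),
            "listModificationFiles": ("GET", self._q_list_mods),
            "saveModificationFile": ("POST", self._q_save_mod),
            "solveFBA": ("GET", self._q_solve_fba),
        }

    def handle(self, method: str, path: str, body: bytes = b"") -> tuple[int, str, bytes]:
        segments = [s for s in path.split("/") if s]
        if not segments:
            return self._json(200, {"server": "fluxvault", "queries": sorted(self._routes())})
        query, params = segments[0], segments[1:]
        routes = self._routes()
        if query not in routes:
            return self._json(404, {"error": "unknown query", "query": query})
        expected_method, handler = routes[query]
        if method != expected_method:
            return self._json(405, {"error": "method not allowed", "query": query})
        log.info("%s /%s %s at %s", method, query, params,
                 datetime.now(timezone.utc).isoformat())
        try:
            return handler(params, body)
        except NotFoundError as exc:
            return self._json(404, {"error": str(exc)})
        except (FormatError, ConflictError, ConsistencyError,
                MissingReferenceError, LineageError) as exc:
            return self._json(400, {"error": str(exc)})
        except FluxVaultError as exc:
            return self._json(500, {"error": str(exc)})

    @staticmethod
    def _json(status: int, payload) -> tuple[int, str, bytes]:
        return status, "application/json", json.dumps(payload).encode()

    # -- queries ----------------------------------------------------------

    def _q_commands(self, params, body) -> tuple[int, str, bytes]:
        return self._json(200, sorted(self.commands.commands))

    def _q_list_models(self, params, body) -> tuple[int, str, bytes]:
        rows = [
            {"model_id": mid, "source_db": db, "n_views": nv, "n_modification_files": nm}
            for mid, db, nv, nm in self.store.list_models()
        ]
        return self._json(200, rows)

    def _q_list_views(self, params, body) -> tuple[int, str, bytes]:
        if len(params) != 1:
            raise FormatError("listViews takes exactly one parameter: model_id")
        return self._json(200, self.store.list_views(params[0]))

    def _q_import_view(self, params, body) -> tuple[int, str, bytes]:
        if len(params) != 1:
            raise FormatError("importViewFile takes exactly one parameter: view_name")
        return 200, CYJS_MEDIA_TYPE, self.store.get_view_bytes(params[0])

    def _q_list_mods(self, params, body) -> tuple[int, str, bytes]:
        if len(params) != 1:
            raise FormatError("listModificationFiles takes exactly one parameter: model_id")
        return self._json(200, self.store.list_modification_files(params[0]))

    def _q_save_mod(self, params, body) -> tuple[int, str, bytes]:
        if len(params) != 1:
            raise FormatError("saveModificationFile takes one parameter: file_name")
        file_name = params[0]
        mod = parse_modification_file(body, file_name)
        if mod.root_model not in {m[0] for m in self.store.list_models()}:
            raise NotFoundError(f"root model {mod.root_model!r} not registered")
        self.store.add_modification_bytes(mod.root_model, file_name, body)
        return self._json(201, {"saved": file_name, "root_model": mod.root_model})

    def _q_solve_fba(self, params, body) -> tuple[int, str, bytes]:
        if not params:
            raise FormatError("solveFBA takes a model_id plus optional modification files")
        model_id, mod_names = params[0], params[1:]
        model = self.store.get_model(model_id)
        files = [
            parse_modification_file(self.store.get_modification_bytes(name), name)
            for name in mod_names
        ]
        state = resolve_effective_state(files, self.store) if files else None
        solution = solve_fba(build_problem(model, state))
        return self._json(
            200,
            {
                "status": solution.status,
                "objective_value": solution.objective_value,
                "fluxes": solution.fluxes,
                "v_min": solution.v_min,
                "v_max": solution.v_max,
            },
        )


def wsgi_app(store: ModelStore):
    """WSGI callable over a store; suitable for any WSGI host."""
    server = QueryServer(store)

    def app(environ, start_response):
        length = int(environ.get("CONTENT_LENGTH") or 0)
        body = environ["wsgi.input"].read(length) if length else b""
        status, media_type, payload = server.handle(
            environ["REQUEST_METHOD"], environ.get("PATH_INFO", "/"), body
        )
        reason = {200: "OK", 201: "Created", 400: "Bad Request", 404: "Not Found",
                  405: "Method Not Allowed", 500: "Internal Server Error"}
        start_response(
            f"{status} {reason.get(status, 'Unknown')}",
            [("Content-Type", media_type), ("Content-Length", str(len(payload)))],
        )
        return [payload]

    return app


def serve(store: ModelStore, host: str = "127.0.0.1", port: int = 8000) -> None:
    """Run the query server on the stdlib WSGI reference server (blocking)."""
    with make_server(host, port, wsgi_app(store)) as httpd:
        log.info("serving on http://%s:%d", host, port)
        httpd.serve_forever()
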