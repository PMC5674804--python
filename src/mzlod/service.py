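"""JSON point service: the backend any viewer client talks to.

Two GET endpoints over a loaded index:

``/api/v1/points?mzmin=&mzmax=&rtmin=&rtmax=&n=``
    The viewport query.  Returns at most ``n`` real stored points (never
    aggregates) as ``{"points": [...], "returned_count": k,
    "truncated": bool}``; ``truncated`` is true when the window held
    more points than the budget.

``/api/v1/bounds``
    The dataset extents and retained point count, for drawing a legend
    of the current view against the whole map.

The index is immutable once loaded, so concurrent reads need no locking
and identical requests always produce byte-identical bodies.  The wire
format is this package's own design; no compatibility with any
particular viewer build is claimed.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, urlsplit

from .model import ViewWindow
from .tree import MzTreeIndex

__all__ = [
    "points_response",
    "bounds_response",
    "make_server",
    "serve",
    "ServiceHandle",
]

_JSON_KW = dict(sort_keys=True, separators=(",", ":"))


def _error(status: int, message: str) -> tuple[int, dict]:
    return status, {"error": message}


def points_response(index: MzTreeIndex | None, params: dict[str, str]
                    ) -> tuple[int, dict]:
    """Core handler for /points; returns (http_status, body_object)."""
    if index is None:
        return _error(503, "no index loaded")
    required = ("mzmin", "mzmax", "rtmin", "rtmax", "n")
    missing = [k for k in required if k not in params]
    if missing:
        return _error(400, f"missing parameter(s): {', '.join(missing)}")
    try:
        mzmin, mzmax = float(params["mzmin"]), float(params["mzmax"])
        rtmin, rtmax = float(params["rtmin"]), float(params["rtmax"])
    except ValueError:
        return _error(400, "viewport parameters must be numeric")
    try:
        n = int(params["n"])
    except ValueError:
        return _error(400, "n must be an integer")
    if n < 0:
        return _error(400, "n must be >= 0")
    if mzmin > mzmax:
        return _error(400, "mzmin must be <= mzmax")
    if rtmin > rtmax:
        return _error(400, "rtmin must be <= rtmax")
    window = ViewWindow(mzmin, mzmax, rtmin, rtmax)
    points, truncated = index.query_points(window, n)
    body = {
        "points": [
            {"id": p.id, "mz": p.mz, "rt": p.rt, "intensity": p.intensity}
            for p in points
        ],
        "returned_count": len(points),
        "truncated": truncated,
    }
    return 200, body


def bounds_response(index: MzTreeIndex | None) -> tuple[int, dict]:
    """Core handler for /bounds."""
    if index is None:
        return _error(503, "no index loaded")
    b = index.bounds
    if b is None:
        body = {"mz_min": 0.0, "mz_max": 0.0, "rt_min": 0.0, "rt_max": 0.0,
                "intensity_max": 0.0, "point_count": 0}
    else:
        body = {
            "mz_min": b.mz_min, "mz_max": b.mz_max,
            "rt_min": b.rt_min, "rt_max": b.rt_max,
            "intensity_max": index.intensity_max,
            "point_count": len(index),
        }
    return 200, body


def _make_handler(index: MzTreeIndex | None):
    class Handler(BaseHTTPRequestHandler):
        protocol_version = "HTTP/1.1"

        def do_GET(self):  # noqa: N802 (http.server API)
            parts = urlsplit(self.path)
            params = {k: v[-1] for k, v in parse_qs(parts.query).items()}
            if parts.path == "/api/v1/points":
                status, body = points_response(index, params)
            elif parts.path == "/api/v1/bounds":
                status, body = bounds_response(index)
            else:
                status, body = _error(404, f"no such endpoint: {parts.path}")
            payload = json.dumps(body, **_JSON_KW).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def log_message(self, fmt, *args):  # quiet by default
            pass

    return Handler


class ServiceHandle:
    """A running service; stop with :meth:`close` or as a context manager."""

    def __init__(self, server: ThreadingHTTPServer):
        self._server = server
        self._thread = threading.Thread(target=server.serve_forever, daemon=True)
        self._thread.start()

    @property
    def host(self) -> str:
        return self._server.server_address[0]

    @property
    def port(self) -> int:
        return self._server.server_address[1]

    @property
    def url(self) -> str:
        return f"http://{self.host}:{self.port}"

    def close(self) -> None:
        self._server.shutdown()
        self._server.server_close()
        self._thread.join(timeout=5)

    def __enter__(self) -> "ServiceHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def make_server(index: MzTreeIndex | None, host: str = "127.0.0.1",
                port: int = 0) -> ThreadingHTTPServer:
    """Bind (but do not start) the HTTP server; port 0 picks a free port."""
    return ThreadingHTTPServer((host, port), _make_handler(index))


def serve(index: MzTreeIndex | None, host: str = "127.0.0.1",
          port: int = 0) -> ServiceHandle:
    """Start serving the index in a background thread; returns a handle."""
    return ServiceHandle(make_server(index, host, port))
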