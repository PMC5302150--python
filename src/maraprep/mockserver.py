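"""In-repo mock of the analysis server's submission endpoint.

The documented client/server contract this mock implements:

* ``POST /submit`` with ``multipart/form-data`` carrying the text fields
  ``data_type``, ``assembly``, ``project``, ``email`` and the summary file
  under the field name ``summary``;
* on success the server answers ``200`` with a ``text/plain`` body that is
  the URL where results will appear (the client stores it as the job's
  download URL);
* any other status is a failed submission.

The mock records every request it accepts (for assertions) and can be told
to fail, which is how error paths are exercised without a real server.
"""

from __future__ import annotations

import threading
from email.message import Message
from email.parser import BytesParser
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer


def _parse_multipart(content_type: str, body: bytes) -> dict[str, bytes]:
    """Parse a multipart/form-data body into {field name: raw bytes}."""
    parser = BytesParser()
    msg = parser.parsebytes(
        f"Content-Type: {content_type}\r\n\r\n".encode() + body
    )
    fields: dict[str, bytes] = {}
    if not msg.is_multipart():
        return fields
    for part in msg.get_payload():
        assert isinstance(part, Message)
        name = part.get_param("name", header="content-disposition")
        if name:
            fields[name] = part.get_payload(decode=True) or b""
    return fields


class _Handler(BaseHTTPRequestHandler):
    def do_POST(self):  # noqa: N802 (http.server API)
        server: MockServer = self.server.owner  # type: ignore[attr-defined]
        if self.path != "/submit":
            self.send_error(404)
            return
        length = int(self.headers.get("Content-Length", "0"))
        body = self.rfile.read(length)
        status = server.next_status()
        if status != 200:
            self.send_response(status)
            self.send_header("Content-Type", "text/plain")
            self.end_headers()
            self.wfile.write(b"simulated failure\n")
            return
        fields = _parse_multipart(self.headers.get("Content-Type", ""), body)
        record = {
            k: v.decode("utf-8", "replace")
            for k, v in fields.items() if k != "summary"
        }
        record["summary"] = fields.get("summary", b"")
        server.received.append(record)
        url = f"{server.url}/results/{len(server.received)}/"
        self.send_response(200)
        self.send_header("Content-Type", "text/plain")
        self.end_headers()
        self.wfile.write(url.encode())

    def log_message(self, *args):  # silence request logging in tests
        pass


class MockServer:
    """Threaded mock endpoint; use as a context manager in tests."""

    def __init__(self):
        self._httpd = ThreadingHTTPServer(("127.0.0.1", 0), _Handler)
        self._httpd.owner = self  # type: ignore[attr-defined]
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, daemon=True
        )
        self.received: list[dict] = []
        self._fail_statuses: list[int] = []

    @property
    def url(self) -> str:
        host, port = self._httpd.server_address[:2]
        return f"http://{host}:{port}"

    def fail_next(self, status: int = 500) -> None:
        """Make the next request answer with the given non-200 status."""
        self._fail_statuses.append(status)

    def next_status(self) -> int:
        return self._fail_statuses.pop(0) if self._fail_statuses else 200

    def __enter__(self) -> "MockServer":
        self._thread.start()
        return self

    def __exit__(self, *exc):
        self._httpd.shutdown()
        self._httpd.server_close()
        return False
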