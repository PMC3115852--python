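"""Key-value configuration shared by the CLI commands.

A config file is plain ``key = value`` lines (``#`` comments allowed).
Recognised keys:

=================  =====================================================
``storage``        ``memory`` or ``sqlite``
``storage_path``   sqlite database file (required for ``sqlite``)
``users``          path to the user-table TSV (login, salt$digest, name)
``ontology_<ID>``  path overriding a bundled term list (SO/MOD/BS/ECO)
``host``/``port``  bind address for ``serve``
``log_level``      python logging level name
=================  =====================================================

Unknown keys are rejected so typos fail loudly at startup; referenced
paths must exist.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .errors import InputError
from .service import UserTable
from .store import AnnotationStore, MemoryBackend, SqliteBackend
from .validation import OntologyTermList, load_bundled_ontologies, \
    load_term_list

_KNOWN_KEYS = {"storage", "storage_path", "users", "host", "port",
               "log_level", "ontology_so", "ontology_mod", "ontology_bs",
               "ontology_eco"}


@dataclass
class Config:
    storage: str = "memory"
    storage_path: str = ""
    users_path: str = ""
    host: str = "127.0.0.1"
    port: int = 8080
    log_level: str = "INFO"
    ontology_paths: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str) -> "Config":
        cfg = cls()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, sep, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if not sep or key not in _KNOWN_KEYS:
                    raise InputError(
                        f"{path}:{lineno}: unknown config key {key!r}")
                if key == "storage":
                    if value not in ("memory", "sqlite"):
                        raise InputError(
                            f"storage must be memory or sqlite, got {value!r}")
                    cfg.storage = value
                elif key == "storage_path":
                    cfg.storage_path = value
                elif key == "users":
                    cfg.users_path = value
                elif key == "host":
                    cfg.host = value
                elif key == "port":
                    cfg.port = int(value)
                elif key == "log_level":
                    cfg.log_level = value
                else:  # ontology_<id>
                    cfg.ontology_paths[key.split("_", 1)[1].upper()] = value
        cfg.check_paths()
        return cfg

    def check_paths(self) -> None:
        for label, path in [("users", self.users_path),
                            *self.ontology_paths.items()]:
            if path and not os.path.exists(path):
                raise InputError(f"configured {label} path does not exist: "
                                 f"{path}")

    def make_store(self) -> AnnotationStore:
        if self.storage == "sqlite":
            if not self.storage_path:
                raise InputError("sqlite storage requires storage_path")
            return AnnotationStore(SqliteBackend(self.storage_path))
        return AnnotationStore(MemoryBackend())

    def make_users(self) -> UserTable:
        if self.users_path:
            return UserTable.from_file(self.users_path)
        return UserTable([])

    def make_ontologies(self) -> dict[str, OntologyTermList]:
        lists = load_bundled_ontologies()
        for oid, path in self.ontology_paths.items():
            lists[oid] = load_term_list(oid, path)
        return lists
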