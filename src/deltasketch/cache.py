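"""Content-addressed caching of sketches and exact k-mer sets.

Building a per-input sketch or k-mer database is the expensive step of
every delta computation; unions and estimates are cheap.  Artifacts are
therefore cached on the file system under a digest of (a) the BLAKE2
checksums of the constituent FASTA files, order-independent, and (b) the
canonicalized sketch parameters (k, backend, precision, hash seed).  Any
byte change in an input or any parameter change yields a new digest; the
same inputs listed in a different order do not.  Cached payloads carry
their own checksum and are rebuilt (with a warning) when it does not
verify, so a corrupted cache can never change results.

Layout: ``<root>/<backend>/k<k>/<digest>.sketch|.kset`` plus a JSON
manifest mapping digests to their constituent paths and parameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from .delta import SketchStack
from .sequences import KmerSet, read_fasta
from .sketch import HllSketch

__all__ = ["CacheKey", "content_key", "SketchCache", "stack_for_paths"]

log = logging.getLogger("deltasketch.cache")

_KSET_MAGIC = b"DSKK"


def _file_digest(path: str | Path) -> str:
    h = hashlib.blake2b(digest_size=20)
    try:
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
    except OSError as e:
        raise OSError(f"cannot read input file {path}: {e}") from e
    return h.hexdigest()


@dataclass(frozen=True)
class CacheKey:
    """Deterministic identity of one cached artifact."""

    digest: str
    component_digests: tuple[tuple[str, str], ...]
    k: int
    backend: str
    p: int
    hash_seed: int

    @property
    def filename(self) -> str:
        ext = "sketch" if self.backend == "sketch" else "kset"
        return f"{self.digest}.{ext}"


def content_key(paths: list[str | Path], k: int, backend: str = "sketch",
                p: int = 14, hash_seed: int = 0) -> CacheKey:
    """Digest of the multiset of file contents plus sketch parameters.

    Per-file digests are sorted before combining, so the key is independent
    of listing order; it changes if any byte of any component changes.
    """
    comp = tuple((str(p_), _file_digest(p_)) for p_ in paths)
    h = hashlib.blake2b(digest_size=20)
    for d in sorted(dig for _, dig in comp):
        h.update(d.encode())
    h.update(f"|k={k}|backend={backend}|p={p}|seed={hash_seed}".encode())
    return CacheKey(h.hexdigest(), comp, k, backend, p, hash_seed)


def _kset_to_bytes(ks: KmerSet) -> bytes:
    packed = ks.members.dtype == np.uint64
    head = _KSET_MAGIC + struct.pack("<BIQ", 0 if packed else 1, ks.k,
                                     ks.cardinality)
    return head + ks.members.tobytes()


def _kset_from_bytes(data: bytes) -> KmerSet:
    if data[:4] != _KSET_MAGIC:
        raise ValueError("not a k-mer set file (bad magic)")
    packed, k, n = struct.unpack("<BIQ", data[4:17])
    dtype = np.uint64 if packed == 0 else np.dtype(f"S{k}")
    members = np.frombuffer(data[17:], dtype=dtype, count=n).copy()
    return KmerSet(k, members)


class SketchCache:
    """File-system cache with an in-process memo and integrity checking."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self._memo: dict[str, HllSketch | KmerSet] = {}
        self.builds = 0  # builder invocations (for instrumentation)
        self.hits = 0

    def _paths(self, key: CacheKey) -> tuple[Path, Path]:
        d = self.root / key.backend / f"k{key.k}"
        return d / key.filename, d / (key.filename + ".meta.json")

    def load_or_build(self, key: CacheKey,
                      builder: Callable[[], HllSketch | KmerSet]
                      ) -> HllSketch | KmerSet:
        """Return the cached artifact for ``key``, building at most once.

        A present-but-corrupt payload (checksum mismatch, truncation) is
        rebuilt with a warning rather than trusted.
        """
        if key.digest in self._memo:
            self.hits += 1
            return self._memo[key.digest]
        payload_path, meta_path = self._paths(key)
        if payload_path.exists():
            try:
                data = payload_path.read_bytes()
                meta = json.loads(meta_path.read_text())
                if hashlib.blake2b(data, digest_size=20).hexdigest() \
                        != meta["payload_digest"]:
                    raise ValueError("payload checksum mismatch")
                art = (HllSketch.from_bytes(data) if key.backend == "sketch"
                       else _kset_from_bytes(data))
                self._memo[key.digest] = art
                self.hits += 1
                return art
            except (ValueError, KeyError, OSError, json.JSONDecodeError) as e:
                warnings.warn(f"cache entry {payload_path.name} is corrupt "
                              f"({e}); rebuilding", stacklevel=2)
        t0 = time.perf_counter()
        art = builder()
        self.builds += 1
        log.debug("built %s (k=%d, backend=%s) in %.3fs", key.digest[:12],
                  key.k, key.backend, time.perf_counter() - t0)
        self._persist(key, art)
        self._memo[key.digest] = art
        return art

    def _persist(self, key: CacheKey, art: HllSketch | KmerSet) -> None:
        payload_path, meta_path = self._paths(key)
        payload_path.parent.mkdir(parents=True, exist_ok=True)
        data = (art.to_bytes() if isinstance(art, HllSketch)
                else _kset_to_bytes(art))
        payload_path.write_bytes(data)
        meta_path.write_text(json.dumps({
            "payload_digest": hashlib.blake2b(data, digest_size=20)
            .hexdigest(),
            "components": {path: dig for path, dig in key.component_digests},
            "k": key.k, "backend": key.backend, "p": key.p,
            "hash_seed": key.hash_seed,
        }, indent=2))
        self._update_manifest(key)

    def _update_manifest(self, key: CacheKey) -> None:
        mpath = self.root / "manifest.json"
        manifest = {}
        if mpath.exists():
            try:
                manifest = json.loads(mpath.read_text())
            except json.JSONDecodeError:
                pass
        manifest[key.digest] = {
            "paths": [path for path, _ in key.component_digests],
            "k": key.k, "backend": key.backend, "p": key.p,
            "hash_seed": key.hash_seed,
        }
        mpath.parent.mkdir(parents=True, exist_ok=True)
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))


class CachedStack(SketchStack):
    """A per-input stack whose per-k entries go through a SketchCache."""

    def __init__(self, paths: list[str | Path], *, backend: str = "sketch",
                 p: int = 14, hash_seed: int = 0, label: str | None = None,
                 cache: SketchCache | None = None):
        colls = [read_fasta(p_) for p_ in paths]
        from .sequences import SequenceCollection
        coll = (colls[0] if len(colls) == 1
                else SequenceCollection.combine(colls))
        super().__init__(coll, backend=backend, p=p, hash_seed=hash_seed,
                         label=label or Path(paths[0]).name)
        self.paths = [str(p_) for p_ in paths]
        self.cache = cache

    def _build(self, k: int):
        if self.cache is None:
            return super()._build(k)
        key = content_key(self.paths, k, self.backend, self.p,
                          self.hash_seed)
        return self.cache.load_or_build(key, lambda: super(CachedStack,
                                                           self)._build(k))


def stack_for_paths(paths: list[str | Path], *, backend: str = "sketch",
                    p: int = 14, hash_seed: int = 0,
                    label: str | None = None,
                    cache: SketchCache | None = None) -> SketchStack:
    """Stack over FASTA file(s), cache-backed when a cache is given."""
    return CachedStack(paths, backend=backend, p=p, hash_seed=hash_seed,
                       label=label, cache=cache)
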