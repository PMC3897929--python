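"""Multi-user pools: private and group collections of containers and
analysis results.

Every user owns exactly one private pool (auto-created).  Groups carry
two authorization levels: NORMAL members read the group pool,
COORDINATORS additionally update it (publish) and manage membership.
Public groups are readable by anyone.  Published entries are immutable
copies taken at publish time — later edits to the source never leak
into a pool, which is what makes the copy/curate/republish workflow
sound.

There is no authentication layer here: users are workspace identities;
real authentication is a deployment concern outside the library.
"""

from __future__ import annotations

import copy
import enum
import itertools
from dataclasses import dataclass, field
from typing import Any


class AuthorizationError(PermissionError):
    """The actor lacks the required access level."""


class AccessLevel(enum.Enum):
    NORMAL = "normal"
    COORDINATOR = "coordinator"


@dataclass
class User:
    id: str
    name: str = ""


@dataclass
class Group:
    id: str
    name: str
    public: bool = False
    members: dict[str, AccessLevel] = field(default_factory=dict)

    def coordinators(self) -> set[str]:
        return {u for u, lvl in self.members.items() if lvl is AccessLevel.COORDINATOR}


@dataclass
class ProcessResult:
    """A stored analysis result (network, enrichment, translation, ...).

    ``descriptor`` records the module and inputs so the payload can be
    recomputed against the same bundle; ``payload`` is the result object
    itself.
    """

    id: str
    module: str
    descriptor: dict
    payload: Any
    owner: str
    created_at: str = ""


@dataclass
class PoolEntry:
    id: str
    kind: str  # "container" | "process"
    item: Any  # immutable copy
    published_by: str
    source_id: str | None = None


@dataclass
class Pool:
    owner: str  # user id or group id
    entries: dict[str, PoolEntry] = field(default_factory=dict)


class TeamSpace:
    """Users, groups and their pools."""

    def __init__(self) -> None:
        self.users: dict[str, User] = {}
        self.groups: dict[str, Group] = {}
        self.private_pools: dict[str, Pool] = {}
        self.group_pools: dict[str, Pool] = {}
        self._entry_ids = itertools.count(1)
        self._group_ids = itertools.count(1)

    # -- identities ------------------------------------------------------

    def add_user(self, user_id: str, name: str = "") -> User:
        if user_id in self.users:
            raise ValueError(f"user {user_id!r} already exists")
        user = User(user_id, name or user_id)
        self.users[user_id] = user
        self.private_pools[user_id] = Pool(owner=user_id)
        return user

    def _user(self, user_id: str) -> User:
        if user_id not in self.users:
            raise KeyError(f"unknown user {user_id!r}")
        return self.users[user_id]

    def _group(self, group_id: str) -> Group:
        if group_id not in self.groups:
            raise KeyError(f"unknown group {group_id!r}")
        return self.groups[group_id]

    def _require_coordinator(self, actor: str, group: Group, action: str) -> None:
        if group.members.get(actor) is not AccessLevel.COORDINATOR:
            raise AuthorizationError(
                f"user {actor!r} is not a coordinator of group {group.id!r} "
                f"and may not {action}"
            )

    # -- group administration ---------------------------------------------

    def create_group(self, actor: str, name: str, public: bool = False) -> Group:
        """Any user may create a group; the creator becomes its coordinator."""
        self._user(actor)
        gid = f"g{next(self._group_ids)}"
        group = Group(gid, name, public=public, members={actor: AccessLevel.COORDINATOR})
        self.groups[gid] = group
        self.group_pools[gid] = Pool(owner=gid)
        return group

    def add_member(
        self, actor: str, group_id: str, user_id: str, level: AccessLevel = AccessLevel.NORMAL
    ) -> Group:
        group = self._group(group_id)
        self._user(user_id)
        self._require_coordinator(actor, group, "add members")
        group.members[user_id] = level
        return group

    def remove_member(self, actor: str, group_id: str, user_id: str) -> Group:
        group = self._group(group_id)
        self._require_coordinator(actor, group, "remove members")
        if user_id not in group.members:
            raise KeyError(f"user {user_id!r} is not a member of {group_id!r}")
        if group.coordinators() == {user_id}:
            raise ValueError(f"cannot remove the last coordinator of group {group_id!r}")
        del group.members[user_id]
        return group

    def set_level(self, actor: str, group_id: str, user_id: str, level: AccessLevel) -> Group:
        group = self._group(group_id)
        self._require_coordinator(actor, group, "change member levels")
        if user_id not in group.members:
            raise KeyError(f"user {user_id!r} is not a member of {group_id!r}")
        if level is AccessLevel.NORMAL and group.coordinators() == {user_id}:
            raise ValueError(f"cannot demote the last coordinator of group {group_id!r}")
        group.members[user_id] = level
        return group

    # -- pools -------------------------------------------------------------

    def deposit(self, actor: str, item: Any, kind: str = "container") -> PoolEntry:
        """Place an item in the actor's own private pool (stored as-is;
        the private pool is the actor's working copy)."""
        self._user(actor)
        entry = PoolEntry(f"e{next(self._entry_ids)}", kind, item, actor)
        self.private_pools[actor].entries[entry.id] = entry
        return entry

    def publish(self, actor: str, entry_id: str, group_id: str) -> PoolEntry:
        """Copy a private-pool entry into a group pool (coordinators only).

        The published entry is a deep copy frozen at publish time.
        """
        group = self._group(group_id)
        self._require_coordinator(actor, group, "publish to the group pool")
        private = self.private_pools[actor]
        if entry_id not in private.entries:
            raise KeyError(f"entry {entry_id!r} is not in {actor!r}'s private pool")
        src = private.entries[entry_id]
        published = PoolEntry(
            f"e{next(self._entry_ids)}",
            src.kind,
            copy.deepcopy(src.item),
            actor,
            source_id=src.id,
        )
        self.group_pools[group_id].entries[published.id] = published
        return published

    def copy_to_private(self, actor: str, group_id: str, entry_id: str) -> PoolEntry:
        """Deep-copy a group-pool entry into the actor's private pool;
        needs read access (membership of the group, or a public group)."""
        group = self._group(group_id)
        self._user(actor)
        if not self.check_access(actor, group_id, "read"):
            raise AuthorizationError(
                f"user {actor!r} may not read the pool of non-public group {group_id!r}"
            )
        pool = self.group_pools[group_id]
        if entry_id not in pool.entries:
            raise KeyError(f"entry {entry_id!r} is not in group {group_id!r}'s pool")
        src = pool.entries[entry_id]
        mine = PoolEntry(
            f"e{next(self._entry_ids)}", src.kind, copy.deepcopy(src.item), actor,
            source_id=src.id,
        )
        self.private_pools[actor].entries[mine.id] = mine
        return mine

    def check_access(self, actor: str, pool_owner: str, intent: str) -> bool:
        """Pure access predicate.  ``pool_owner`` is a user id (private
        pool) or group id.  read <= membership | public | ownership;
        update <= coordinator | ownership."""
        if intent not in ("read", "update"):
            raise ValueError(f"intent must be 'read' or 'update', got {intent!r}")
        if pool_owner in self.users:
            return actor == pool_owner
        group = self._group(pool_owner)
        if intent == "read":
            return group.public or actor in group.members
        return group.members.get(actor) is AccessLevel.COORDINATOR
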