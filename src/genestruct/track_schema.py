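"""Pydantic models defining the feature-track JSON document schema.

The JSON Schema shipped at ``schemas/feature_tracks.schema.json`` is the
canonical on-disk description; these models are the executable validator.
"""

from __future__ import annotations

from typing import Dict, List

from pydantic import BaseModel, ConfigDict, Field


class FeatureModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    start: int = Field(ge=1)
    end: int = Field(ge=1)
    type: str
    label: str
    attributes: Dict[str, str] = {}


class TrackModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str
    provenance: str
    color_hint: str
    features: List[FeatureModel]


class TrackDocument(BaseModel):
    model_config = ConfigDict(extra="forbid")

    accession: str
    length: int = Field(ge=1)
    tracks: List[TrackModel]
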