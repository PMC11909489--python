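{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "gamekin/trial_schema_v1.json",
  "title": "gamekin trial file, version 1",
  "description": "Top-level list of trial objects. Times are seconds from trial start; coordinates are screen points, origin top-left, x rightward, y downward.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["trial_id", "game", "hand", "task", "traces"],
    "properties": {
      "trial_id": {"type": "string"},
      "game": {"enum": ["market", "race", "filling", "message", "round"]},
      "hand": {"enum": ["left", "right", "both"]},
      "attempt_index": {"type": "integer", "minimum": 1, "default": 1},
      "age_years": {"type": ["number", "null"]},
      "device": {
        "type": "object",
        "properties": {
          "points_per_inch": {"type": "number", "exclusiveMinimum": 0, "default": 132},
          "screen_width_pt": {"type": "number", "exclusiveMinimum": 0, "default": 1366},
          "screen_height_pt": {"type": "number", "exclusiveMinimum": 0, "default": 1024}
        }
      },
      "task": {
        "type": "object",
        "description": "Game-specific task spec (see gamekin.tasks.task_to_dict): market items with start/box geometry; race track polyline + 12 manual breakpoints + corridor width; filling shapes; message text + Morse map + dot/dash boundary + target circle + switch time; round mode + two circles + duration."
      },
      "traces": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["pointer_id", "samples"],
          "properties": {
            "pointer_id": {"type": "integer"},
            "samples": {
              "type": "array",
              "minItems": 1,
              "items": {
                "type": "object",
                "required": ["t", "x", "y"],
                "properties": {
                  "t": {"type": "number", "minimum": 0},
                  "x": {"type": "number"},
                  "y": {"type": "number"},
                  "event": {"enum": ["down", "move", "up"], "default": "move"}
                }
              }
            }
          }
        }
      },
      "meta": {"type": "object", "description": "Free-form; unknown keys are ignored on read."}
    }
  }
}
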