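{
  "$defs": {
    "axis": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "label": {"type": "string"},
        "limits": {"type": "array", "items": {"type": "number"}},
        "tick_positions": {"type": "array"},
        "tick_labels": {"type": "array"},
        "log_scale": {"type": ["number", "null"]}
      }
    },
    "legend": {
      "type": ["object", "null"],
      "additionalProperties": false,
      "required": ["entries"],
      "properties": {
        "title": {"type": "string"},
        "entries": {
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["label", "colour", "glyph"],
            "properties": {
              "label": {"type": "string"},
              "colour": {"type": "string"},
              "glyph": {"enum": ["box", "dot", "line"]}
            }
          }
        }
      }
    },
    "chart": {
      "type": "object",
      "additionalProperties": false,
      "required": ["chart_type"],
      "properties": {
        "chart_type": {
          "enum": ["density", "boxplot", "violin", "segplot", "stripplot",
                   "barplot", "scatterplot", "histogram", "qq_fit",
                   "qq_comparison", "manhattan", "polygonplot", "heatmap",
                   "dotmap", "hexbinplot"]
        },
        "data": {"type": "string"},
        "title": {"type": "string"},
        "data_binding": {"type": "object", "additionalProperties": true},
        "aesthetics": {"type": "object", "additionalProperties": true},
        "x_axis": {"$ref": "#/$defs/axis"},
        "y_axis": {"$ref": "#/$defs/axis"},
        "legend": {"$ref": "#/$defs/legend"},
        "theme_overrides": {"type": "object", "additionalProperties": true}
      }
    },
    "layout": {
      "type": "object",
      "additionalProperties": false,
      "required": ["n_rows", "n_cols", "placements"],
      "properties": {
        "n_rows": {"type": "integer"},
        "n_cols": {"type": "integer"},
        "placements": {
          "type": "array",
          "items": {
            "type": "object",
            "additionalProperties": false,
            "required": ["panel_index", "row", "col"],
            "properties": {
              "panel_index": {"type": "integer"},
              "row": {"type": "integer"},
              "col": {"type": "integer"},
              "row_span": {"type": "integer"},
              "col_span": {"type": "integer"}
            }
          }
        },
        "row_heights": {"type": "array", "items": {"type": "number"}},
        "col_widths": {"type": "array", "items": {"type": "number"}},
        "shared_x_groups": {"type": "array"},
        "shared_y_groups": {"type": "array"},
        "spacing": {"type": "number"},
        "axis_label_policy": {"enum": ["edge", "all"]}
      }
    },
    "theme": {"type": "object", "additionalProperties": true}
  },
  "type": "object",
  "additionalProperties": false,
  "required": ["version", "kind", "body"],
  "properties": {
    "version": {"type": "string"},
    "kind": {"enum": ["chart", "multiplot"]},
    "seed": {"type": ["integer", "null"]},
    "body": {"type": "object", "additionalProperties": true}
  },
  "bodies": {
    "chart": {"$ref": "#/$defs/chart"},
    "multiplot": {
      "type": "object",
      "additionalProperties": false,
      "required": ["panels", "layout"],
      "properties": {
        "kind": {"enum": ["multiplot"]},
        "panels": {"type": "array", "items": {"$ref": "#/$defs/chart"}},
        "layout": {"$ref": "#/$defs/layout"},
        "theme": {"$ref": "#/$defs/theme"}
      }
    }
  }
}
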