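{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "chipflow network description",
  "type": "object",
  "additionalProperties": false,
  "required": ["nodes", "channels", "pumps", "fluids"],
  "$defs": {
    "quantity": {
      "oneOf": [
        {"type": "number"},
        {
          "type": "object",
          "additionalProperties": false,
          "required": ["value", "unit"],
          "properties": {"value": {"type": "number"}, "unit": {"type": "string"}}
        }
      ]
    }
  },
  "properties": {
    "nodes": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id"],
        "properties": {
          "id": {"type": "string"},
          "ground": {"type": "boolean"},
          "sink": {"type": "boolean"}
        }
      }
    },
    "channels": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "node_a", "node_b", "width", "height", "length"],
        "properties": {
          "id": {"type": "string"},
          "node_a": {"type": "string"},
          "node_b": {"type": "string"},
          "width": {"$ref": "#/$defs/quantity"},
          "height": {"$ref": "#/$defs/quantity"},
          "length": {"$ref": "#/$defs/quantity"}
        }
      }
    },
    "pumps": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "node_from", "node_to", "kind", "value"],
        "properties": {
          "id": {"type": "string"},
          "node_from": {"type": "string"},
          "node_to": {"type": "string"},
          "kind": {"enum": ["flow_rate", "pressure"]},
          "value": {"$ref": "#/$defs/quantity"}
        }
      }
    },
    "fluids": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "viscosity"],
        "properties": {
          "id": {"type": "string"},
          "viscosity": {"$ref": "#/$defs/quantity"},
          "continuous_phase": {"type": "boolean"}
        }
      }
    },
    "species": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "diffusion_coefficient"],
        "properties": {
          "id": {"type": "string"},
          "diffusion_coefficient": {"$ref": "#/$defs/quantity"}
        }
      }
    },
    "injections": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["node", "species_concentrations"],
        "properties": {
          "node": {"type": "string"},
          "species_concentrations": {
            "type": "object",
            "additionalProperties": {"$ref": "#/$defs/quantity"}
          },
          "t_start": {"$ref": "#/$defs/quantity"},
          "t_end": {"$ref": "#/$defs/quantity"}
        }
      }
    },
    "droplets": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "length", "channel"],
        "properties": {
          "id": {"type": "string"},
          "length": {"$ref": "#/$defs/quantity"},
          "b": {"type": "number"},
          "channel": {"type": "string"},
          "t_inject": {"$ref": "#/$defs/quantity"}
        }
      }
    },
    "membranes": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "channel", "area", "pore_radius", "porosity", "thickness", "tank_volume"],
        "properties": {
          "id": {"type": "string"},
          "channel": {"type": "string"},
          "area": {"$ref": "#/$defs/quantity"},
          "pore_radius": {"$ref": "#/$defs/quantity"},
          "porosity": {"type": "number", "minimum": 0, "exclusiveMaximum": 1},
          "thickness": {"$ref": "#/$defs/quantity"},
          "tank_volume": {"$ref": "#/$defs/quantity"},
          "model": {"enum": ["pore_discovery"]}
        }
      }
    },
    "settings": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "max_time": {"$ref": "#/$defs/quantity"},
        "fixed_step": {"$ref": "#/$defs/quantity"},
        "modules": {
          "type": "array",
          "items": {"enum": ["mixing", "droplets", "membranes"]}
        },
        "max_events": {"type": "integer", "minimum": 1},
        "terminate_on_droplet_exit": {"type": "boolean"},
        "record": {"enum": ["events", "final"]}
      }
    }
  }
}
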