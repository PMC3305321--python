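<?xml version="1.0" encoding="utf-8"?>
<!-- Sample of the annotation XML dialect the package reads: one Annotation
     element per layer (layer name = Gleason grade of the outlined cancer
     regions), Region/Vertices/Vertex with X/Y pixel coordinates, and
     NegativeROA="1" marking a negative-pen exclusion region. -->
<Annotations>
  <Annotation Name="3+4">
    <Regions>
      <Region Text="3+4" NegativeROA="0">
        <Vertices>
          <Vertex X="120.0" Y="85.0"/>
          <Vertex X="460.5" Y="92.0"/>
          <Vertex X="505.0" Y="340.0"/>
          <Vertex X="300.0" Y="455.5"/>
          <Vertex X="98.0" Y="310.0"/>
        </Vertices>
      </Region>
    </Regions>
  </Annotation>
  <Annotation Name="4+3">
    <Regions>
      <Region Text="4+3" NegativeROA="0">
        <Vertices>
          <Vertex X="600.0" Y="400.0"/>
          <Vertex X="780.0" Y="420.0"/>
          <Vertex X="740.0" Y="600.0"/>
          <Vertex X="590.0" Y="560.0"/>
        </Vertices>
      </Region>
      <Region Text="artifact" NegativeROA="1">
        <Vertices>
          <Vertex X="650.0" Y="470.0"/>
          <Vertex X="690.0" Y="470.0"/>
          <Vertex X="690.0" Y="510.0"/>
          <Vertex X="650.0" Y="510.0"/>
        </Vertices>
      </Region>
    </Regions>
  </Annotation>
</Annotations>
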