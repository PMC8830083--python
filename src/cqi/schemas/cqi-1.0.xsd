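<?xml version="1.0" encoding="UTF-8"?>
<!-- Interchange schema for clinical quality indicator artifacts, v1.0.
     Expression logic travels as canonical indicator-language text inside
     the predicate, default and define elements. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:simpleType name="StatusType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="DRAFT"/>
      <xs:enumeration value="REVIEWING"/>
      <xs:enumeration value="PUBLISHED"/>
      <xs:enumeration value="DEPRECATED"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="ParamType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="Interval&lt;DateTime&gt;"/>
      <xs:enumeration value="DateTime"/>
      <xs:enumeration value="Integer"/>
      <xs:enumeration value="Decimal"/>
      <xs:enumeration value="String"/>
      <xs:enumeration value="Code"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="indicator">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="name" type="xs:string"/>
              <xs:element name="version" type="xs:string"/>
              <xs:element name="language" type="xs:string"/>
              <xs:element name="translation" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
              <xs:element name="description" type="xs:string"/>
              <xs:element name="status" type="StatusType"/>
              <xs:element name="author" type="xs:string"/>
              <xs:element name="time" type="xs:dateTime" minOccurs="0"/>
              <xs:element name="email" type="xs:string"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="terminology" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="binding" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="term" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="system" type="xs:string" use="required"/>
                        <xs:attribute name="code" type="xs:string" use="required"/>
                        <xs:attribute name="uri" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="localCode" type="xs:string" use="required"/>
                  <xs:attribute name="sourceArchetype" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="archetypes">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="binding" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="element" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="code" type="xs:string" use="required"/>
                        <xs:attribute name="path" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="predicate" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
                  </xs:sequence>
                  <xs:attribute name="alias" type="xs:string" use="required"/>
                  <xs:attribute name="archetypeId" type="xs:string" use="required"/>
                  <xs:attribute name="templateId" type="xs:string"/>
                  <xs:attribute name="slotPath" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="logic">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="parameter" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="default" type="xs:string" minOccurs="0"/>
                  </xs:sequence>
                  <xs:attribute name="name" type="xs:string" use="required"/>
                  <xs:attribute name="type" type="ParamType" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="define" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="name" type="xs:string" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="schemaVersion" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
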